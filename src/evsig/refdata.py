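"""Published reference quantities for the UC-vs-NBI isolation comparison.

Small printed tables from the EV isolation-method comparison this analysis
builds on, transcribed as in-memory data so the corresponding metrics can be
recomputed without any download: the apolipoprotein label-free-quantification
(LFQ) table for ultracentrifugation (UC) versus nickel-based isolation (NBI),
the TRPS particle-yield measurements, and the proteome-overlap counts.

LFQ intensities are in units of 1e7 normalized peak intensity (mean +/- SEM
over three replicate isolations); proteins not found in NBI samples are
marked undetected.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "apolipoprotein_lfq",
    "APOLIPOPROTEIN_ACCESSIONS",
    "TRPS_PARTICLES_PER_ML",
    "PROTEINS_IDENTIFIED_TOTAL",
    "PROTEINS_SHARED",
]

# (protein name, accession, UC mean, UC sem, NBI mean, NBI sem); NBI None = ND
_APOLIPO_ROWS = [
    ("Apolipoprotein A-I", "APOA1_HUMAN", 249.0, 21.0, 57.0, 5.5),
    ("Apolipoprotein A-II", "APOA2_HUMAN", 2.8, 0.4, 0.1, 0.0),
    ("Apolipoprotein A-IV", "APOA4_HUMAN", 6.9, 1.5, None, None),
    ("Apolipoprotein B-100", "APOB_HUMAN", 628.0, 14.0, 64.0, 8.2),
    ("Apolipoprotein C-I", "APOC1_HUMAN", 0.6, 0.0, None, None),
    ("Apolipoprotein C-II", "APOC2_HUMAN", 0.1, 0.0, None, None),
    ("Apolipoprotein C-III", "APOC3_HUMAN", 4.0, 0.3, None, None),
    ("Apolipoprotein D", "APOD_HUMAN", 4.7, 0.7, None, None),
    ("Apolipoprotein E", "APOE_HUMAN", 7.0, 0.7, None, None),
    ("Apolipoprotein L1", "APOL1_HUMAN", 0.4, 0.0, None, None),
    ("Apolipoprotein M", "APOLM_HUMAN", 0.1, 0.0, None, None),
    ("Apolipoprotein(a)", "APOA_HUMAN", 0.5, 0.1, None, None),
]

APOLIPOPROTEIN_ACCESSIONS = frozenset(r[1] for r in _APOLIPO_ROWS)

#: TRPS particle yields (particles/mL) by nanopore and isolation method.
TRPS_PARTICLES_PER_ML = {
    "NP200": {"NBI": 5.2e9, "UC": 1.2e9},
    "NP400": {"NBI": 8.8e7, "UC": 5.7e7},
}

#: Proteome comparison of the two isolation methods.
PROTEINS_IDENTIFIED_TOTAL = 107
PROTEINS_SHARED = 60


def apolipoprotein_lfq() -> pd.DataFrame:
    """Long-format apolipoprotein LFQ table (columns: protein, accession,
    group, mean_lfq, sem, detected)."""
    records = []
    for name, acc, uc_mean, uc_sem, nbi_mean, nbi_sem in _APOLIPO_ROWS:
        records.append((name, acc, "UC", uc_mean, uc_sem, True))
        records.append(
            (name, acc, "NBI", 0.0 if nbi_mean is None else nbi_mean,
             0.0 if nbi_sem is None else nbi_sem, nbi_mean is not None)
        )
    return pd.DataFrame(
        records,
        columns=["protein", "accession", "group", "mean_lfq", "sem", "detected"],
    )
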
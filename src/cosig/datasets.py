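"""Published cohort bookkeeping used for worked examples and checks.

The TCGA breast (BRCA), ovarian (OV) and endometrial (UCEC) projects
provide, per their public sample manifests: 1,102 BRCA primary tumors (12
of them from male patients) and 113 BRCA solid-tissue normals; 374 OV
tumors and no OV solid-tissue normals; 551 UCEC tumors and 35 UCEC
normals — 2,175 samples in total.  Restricting to female samples leaves
2,015 tumors and 148 normals (2,163 samples).  This module materializes
that bookkeeping as a metadata table so the sample-filtering arithmetic can
be exercised without downloading anything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix, validate_sample_table

TCGA_COHORTS = {
    # cohort: (n_tumor, n_tumor_male, n_normal)
    "TCGA-BRCA": (1102, 12, 113),
    "TCGA-OV": (374, 0, 0),
    "TCGA-UCEC": (551, 0, 35),
}


def tcga_female_cancers_sample_table() -> pd.DataFrame:
    """Metadata table mirroring the three TCGA cohorts' sample manifests."""
    rows = []
    for cohort, (n_tumor, n_male, n_normal) in TCGA_COHORTS.items():
        for i in range(n_tumor):
            rows.append(
                {
                    "sample_id": f"{cohort}-T{i:04d}",
                    "patient_id": f"{cohort}-P{i:04d}",
                    "cohort": cohort,
                    "sample_type": "tumor",
                    "sex": "male" if i < n_male else "female",
                }
            )
        for i in range(n_normal):
            rows.append(
                {
                    "sample_id": f"{cohort}-N{i:04d}",
                    "patient_id": f"{cohort}-PN{i:04d}",
                    "cohort": cohort,
                    "sample_type": "normal",
                    "sex": "female",
                }
            )
    return validate_sample_table(pd.DataFrame(rows))


def stub_counts_for(meta: pd.DataFrame, n_genes: int = 2) -> CountMatrix:
    """A minimal deterministic count matrix aligned to a metadata table.

    Only the column labels matter for sample-accounting exercises; values
    are a small deterministic pattern.
    """
    samples = list(meta["sample_id"])
    genes = [f"G{i}" for i in range(n_genes)]
    values = (np.arange(n_genes)[:, None] + np.arange(len(samples))[None, :]) % 7 + 1
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))
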
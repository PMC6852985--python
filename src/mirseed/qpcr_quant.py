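"""Relative quantification from qPCR Ct tables via the 2^-ddCt method.

Technical replicates are averaged per biological sample; dCt is the
target Ct minus the reference-gene (housekeeping) Ct of the same
sample; ddCt subtracts the mean dCt of the calibrator genotype; the
relative expression is 2^-ddCt (amplification efficiency assumed 2.0).
Genotype means are compared with a two-sample Student's t-test
(Welch's variant by flag); p < 0.05 is flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample", "genotype", "assay", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a TSV of Ct measurements (one row per well).

    Required columns: sample, genotype, assay, ct.  Multiple rows per
    (sample, assay) are technical replicates.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def ddct(
    records: pd.DataFrame,
    target_assay: str,
    reference_assay: str = "actin",
    calibrator_genotype: Optional[str] = None,
) -> pd.DataFrame:
    """Per-sample relative expression of a target assay.

    Returns a frame indexed by sample with genotype, dct, ddct and
    relative_expression columns.  Every sample must carry both the
    target and the reference assay.
    """
    if calibrator_genotype is None:
        raise ValueError("calibrator_genotype is required")
    mean_ct = (
        records.groupby(["sample", "genotype", "assay"], sort=True)["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample", "genotype"], columns="assay", values="ct")
    for assay in (target_assay, reference_assay):
        if assay not in wide.columns or wide[assay].isna().any():
            missing = (
                wide.index.get_level_values("sample").tolist()
                if assay not in wide.columns
                else wide.index[wide[assay].isna()].get_level_values("sample").tolist()
            )
            raise ValueError(f"assay {assay!r} missing for samples {missing}")
    out = wide.reset_index()[["sample", "genotype"]].copy()
    out["dct"] = (wide[target_assay] - wide[reference_assay]).to_numpy()
    calib = out[out["genotype"] == calibrator_genotype]
    if calib.empty:
        raise ValueError(f"no samples for calibrator genotype {calibrator_genotype!r}")
    calibrator_mean = calib["dct"].mean()
    out["ddct"] = out["dct"] - calibrator_mean
    out["relative_expression"] = 2.0 ** (-out["ddct"])
    return out.set_index("sample")


@dataclass
class GenotypeComparison:
    t_statistic: float
    p_value: float
    significant: bool
    genotypes: Tuple[str, str]


def compare_genotypes(
    expression: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
) -> GenotypeComparison:
    """Two-sided two-sample t-test on per-sample relative expression.

    ``expression`` is the output of :func:`ddct`; exactly two genotypes
    with >= 2 biological samples each are required.
    """
    genotypes = sorted(expression["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError(f"expected exactly two genotypes, got {genotypes}")
    a = expression.loc[expression["genotype"] == genotypes[0], "relative_expression"]
    b = expression.loc[expression["genotype"] == genotypes[1], "relative_expression"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each genotype needs at least two biological samples")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GenotypeComparison(
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        genotypes=(genotypes[0], genotypes[1]),
    )
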
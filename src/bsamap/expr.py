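"""Relative qRT-PCR expression: ΔCt, ΔΔCt, 2^-ΔΔCt, and line comparison.

Technical replicates are averaged per (sample, gene, biological
replicate); ΔCt = mean Ct(target) - mean Ct(reference gene); ΔΔCt
subtracts the calibrator line's mean ΔCt (per tissue); the fold change
is 2^-ΔΔCt under the perfect-doubling (efficiency 2.0) model.  Lines
are compared per tissue with a two-sample Student's t-test on the
per-biological-replicate ΔCt values (statistically equivalent, up to
sign, to testing log2 fold changes); Welch's variant is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "delta_ct",
    "fold_change",
    "compare_lines",
    "relative_expression",
]

CT_COLUMNS = ["sample", "line", "tissue", "gene", "bio_rep", "tech_rep", "ct"]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return records


def delta_ct(
    records: pd.DataFrame,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> pd.DataFrame:
    """ΔCt per (line, tissue, biological replicate).

    Technical replicates are averaged (mean) per gene first; then
    ΔCt = Ct(target) - Ct(reference).  Every (line, tissue, bio_rep)
    must carry the reference gene.
    """
    records = _validate(records)
    keys = ["line", "tissue", "bio_rep"]
    means = (
        records[records["gene"].isin([target_gene, reference_gene])]
        .groupby(keys + ["gene"], sort=False)["ct"].mean().unstack("gene")
    )
    if reference_gene not in means.columns or means[reference_gene].isna().any():
        bad = means.index[means.get(reference_gene, pd.Series(dtype=float)).isna()].tolist() \
            if reference_gene in means.columns else means.index.tolist()
        raise ValueError(f"missing reference gene {reference_gene!r} for {bad}")
    if target_gene not in means.columns or means[target_gene].isna().any():
        raise ValueError(f"missing target gene {target_gene!r} for some replicates")
    out = means.reset_index()
    out["delta_ct"] = out[target_gene] - out[reference_gene]
    return out[keys + ["delta_ct"]]


def fold_change(delta_ct_sample: float, delta_ct_calibrator: float) -> float:
    """2^-ΔΔCt with ΔΔCt = ΔCt(sample) - ΔCt(calibrator)."""
    return float(2.0 ** -(delta_ct_sample - delta_ct_calibrator))


def compare_lines(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample Student's t-test (Welch optional); two-sided p.

    Intended for per-biological-replicate ΔCt values of the two lines.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 biological replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def relative_expression(
    records: pd.DataFrame,
    calibrator_line: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
    test_on: str = "delta_ct",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-tissue relative expression of each line versus a calibrator.

    Returns one row per (tissue, line) with mean fold change +/- SD over
    biological replicates (calibrated to the calibrator line's mean ΔCt
    in that tissue) and, for the non-calibrator line, the t statistic
    and two-sided p of the between-line comparison.  ``test_on`` selects
    ``delta_ct`` (default) or ``log2_fold`` — the two give identical
    |t| because the transformation is affine.
    """
    dct = delta_ct(records, target_gene=target_gene, reference_gene=reference_gene)
    lines = dct["line"].unique().tolist()
    if calibrator_line not in lines:
        raise ValueError(f"calibrator line {calibrator_line!r} absent from the data")
    rows = []
    for tissue, sub in dct.groupby("tissue", sort=False):
        cal = sub.loc[sub["line"] == calibrator_line, "delta_ct"].to_numpy()
        if cal.size == 0:
            raise ValueError(f"calibrator line has no replicates in tissue {tissue!r}")
        cal_mean = cal.mean()
        for line, line_sub in sub.groupby("line", sort=False):
            d = line_sub["delta_ct"].to_numpy()
            folds = 2.0 ** -(d - cal_mean)
            t = p = np.nan
            if line != calibrator_line:
                if test_on == "delta_ct":
                    t, p = compare_lines(d, cal, equal_var=equal_var)
                elif test_on == "log2_fold":
                    t, p = compare_lines(
                        -(d - cal_mean), -(cal - cal_mean), equal_var=equal_var
                    )
                else:
                    raise ValueError(f"unknown test_on {test_on!r}")
            rows.append({
                "tissue": tissue, "line": line, "n_bio_reps": d.size,
                "mean_fold": folds.mean(), "sd_fold": folds.std(ddof=1) if d.size > 1 else 0.0,
                "mean_delta_ct": d.mean(), "t": t, "p": p,
            })
    return pd.DataFrame(rows)
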
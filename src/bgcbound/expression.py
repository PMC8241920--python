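"""Comparative-CT (delta-delta-CT) relative expression with per-gene classes.

Quantification follows the standard comparative CT method assuming
amplification efficiency of exactly 2: technical replicates are averaged
first (they are not independent), each biological replicate yields
dCT = CT_target - CT_reference, and the fold change of the case strain
relative to the calibrator is 2^-(mean dCT_case - mean dCT_calibrator).
Significance is a one-way fixed-effects ANOVA across the two strains'
per-biological-replicate relative values (for two groups this is exactly
the pooled-variance t-test, t^2 = F).  Undetermined CT values are carried
as detection flags and never imputed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["strain", "gene", "bio_rep", "tech_rep", "ct"]


class ExpressionError(ValueError):
    pass


class DetectionStatus(enum.Enum):
    DETECTED = "detected"
    NOT_IN_CALIBRATOR = "not_in_calibrator"   # undetermined in every calibrator replicate
    NOT_IN_CASE = "not_in_case"               # detected in calibrator, lost in the case strain


class RegClass(enum.Enum):
    ABOLISHED = "abolished"
    DOWNREGULATED = "downregulated"
    UNCHANGED = "unchanged"
    UPREGULATED = "upregulated"
    NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class ExpressionThresholds:
    """Fold-change cutoffs mapping the qualitative regulation classes.

    'Almost completely abolished' is fc <= 0.1, 'moderately downregulated'
    fc in (0.1, 2/3], upregulated fc >= 1.5 — all requiring p < alpha.
    Anything else, including significant fold changes inside (2/3, 1.5),
    is 'unchanged'.
    """

    alpha: float = 0.05
    abolished_max: float = 0.1
    downregulated_max: float = 2.0 / 3.0
    upregulated_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.abolished_max < self.downregulated_max < self.upregulated_min):
            raise ExpressionError("thresholds must satisfy 0 < abolished < down < up")
        if not (0 < self.alpha < 1):
            raise ExpressionError("alpha must lie in (0, 1)")


DEFAULT_THRESHOLDS = ExpressionThresholds()


@dataclass
class ExpressionResult:
    gene: str
    fold_change: float        # NaN when not expressed
    p_value: float            # NaN when not expressed
    reg_class: RegClass


def load_ct_table(path) -> pd.DataFrame:
    """Read a CT table CSV; blank ct fields mean 'undetermined'."""
    df = pd.read_csv(path, dtype={"strain": str, "gene": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionError(f"CT table lacks columns: {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df[CT_COLUMNS].copy()


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    bad = df["ct"].dropna()
    if ((bad <= 0) | (bad > 45)).any():
        raise ExpressionError("determined CT values must lie in (0, 45]")
    return df


def _tech_means(df: pd.DataFrame, strain: str, gene: str) -> pd.Series:
    """Mean CT per biological replicate (technical replicates averaged first).

    A replicate with no determined technical CT is NaN (undetermined).
    """
    sub = df[(df["strain"] == strain) & (df["gene"] == gene)]
    if sub.empty:
        raise ExpressionError(f"no CT rows for gene {gene!r} in strain {strain!r}")
    return sub.groupby("bio_rep")["ct"].mean()


def detection_status(df: pd.DataFrame, gene: str,
                     strain_case: str, strain_calibrator: str) -> DetectionStatus:
    cal = _tech_means(df, strain_calibrator, gene)
    if cal.isna().all():
        return DetectionStatus.NOT_IN_CALIBRATOR
    case = _tech_means(df, strain_case, gene)
    if case.isna().all():
        return DetectionStatus.NOT_IN_CASE
    return DetectionStatus.DETECTED


def relative_expression(df: pd.DataFrame, gene: str, ref_gene: str,
                        strain_case: str, strain_calibrator: str):
    """Fold change (case vs calibrator) and per-biological-replicate values.

    Returns ``(fold_change, rel_case, rel_calibrator)`` where the relative
    values are 2^-(dCT - mean dCT of the calibrator), so the calibrator
    centers on 1.  Biological replicates whose target CT is undetermined are
    dropped; an undetermined reference CT is a hard error.
    """
    out = {}
    for strain in (strain_calibrator, strain_case):
        ref = _tech_means(df, strain, ref_gene)
        if ref.isna().any():
            raise ExpressionError(
                f"reference gene {ref_gene!r} undetermined in strain {strain!r}"
            )
        tgt = _tech_means(df, strain, gene)
        dct = (tgt - ref.reindex(tgt.index)).dropna()
        if dct.empty:
            raise ExpressionError(
                f"gene {gene!r} undetermined in every replicate of strain {strain!r}"
            )
        out[strain] = dct
    base = out[strain_calibrator].mean()
    ddct = out[strain_case].mean() - base
    fold = 2.0 ** (-ddct)
    rel_case = (2.0 ** (-(out[strain_case] - base))).to_numpy()
    rel_cal = (2.0 ** (-(out[strain_calibrator] - base))).to_numpy()
    return fold, rel_case, rel_cal


def anova_p(values_case, values_calibrator) -> float:
    """One-way fixed-effects ANOVA p across the two strains' replicate values.

    Degenerate zero-variance groups: p = 1.0 for identical means, 0.0
    otherwise (the F statistic diverges).
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_calibrator, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ExpressionError("ANOVA needs at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.f_oneway(a, b).pvalue)


def classify_gene(fold_change: float, p_value: float,
                  detection: DetectionStatus = DetectionStatus.DETECTED,
                  thresholds: ExpressionThresholds = DEFAULT_THRESHOLDS) -> RegClass:
    """Assign the single regulation class for a gene.

    The classes partition the (fold change, p, detection) space: detection
    failures short-circuit, then significance gates the fold-change bands.
    """
    if detection is DetectionStatus.NOT_IN_CALIBRATOR:
        return RegClass.NOT_EXPRESSED
    if detection is DetectionStatus.NOT_IN_CASE:
        return RegClass.ABOLISHED
    significant = (not math.isnan(p_value)) and p_value < thresholds.alpha
    if significant and fold_change <= thresholds.abolished_max:
        return RegClass.ABOLISHED
    if significant and fold_change <= thresholds.downregulated_max:
        return RegClass.DOWNREGULATED
    if significant and fold_change >= thresholds.upregulated_min:
        return RegClass.UPREGULATED
    return RegClass.UNCHANGED


def analyze_locus(df: pd.DataFrame, ref_gene: str, strain_case: str,
                  strain_calibrator: str,
                  thresholds: ExpressionThresholds = DEFAULT_THRESHOLDS) -> list[ExpressionResult]:
    """One ExpressionResult per assayed gene (reference excluded), table order."""
    validate_ct_table(df)
    genes = list(dict.fromkeys(df["gene"]))
    if ref_gene not in genes:
        raise ExpressionError(f"reference gene {ref_gene!r} absent from the CT table")
    for strain in (strain_case, strain_calibrator):
        if not (df["strain"] == strain).any():
            raise ExpressionError(f"strain {strain!r} absent from the CT table")
    results = []
    for gene in genes:
        if gene == ref_gene:
            continue
        status = detection_status(df, gene, strain_case, strain_calibrator)
        if status is not DetectionStatus.DETECTED:
            cls = classify_gene(float("nan"), float("nan"), status, thresholds)
            results.append(ExpressionResult(gene, float("nan"), float("nan"), cls))
            continue
        fold, rel_case, rel_cal = relative_expression(
            df, gene, ref_gene, strain_case, strain_calibrator
        )
        p = anova_p(rel_case, rel_cal) if min(len(rel_case), len(rel_cal)) >= 2 else float("nan")
        cls = classify_gene(fold, p, status, thresholds)
        results.append(ExpressionResult(gene, fold, p, cls))
    return results


def write_results(results: list[ExpressionResult], path) -> None:
    rows = [
        {"gene": r.gene, "fold_change": r.fold_change,
         "p_value": r.p_value, "reg_class": r.reg_class.value}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
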
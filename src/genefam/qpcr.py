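"""Relative qPCR expression: standard curves, ddCt fold changes, t-tests.

The workhorse is the comparative-Ct (2^-ddCt) method: per replicate the
target gene's threshold cycle is normalised by a housekeeping reference
measured in the same sample (dCt = Ct_target - Ct_reference), then each
sample's mean dCt is referred to a calibrator sample
(ddCt = mean dCt_sample - mean dCt_calibrator) and expressed as a fold
change 2^-ddCt.  The calibrator's own fold change is exactly 1.

Significance between samples is assessed on the replicate dCt values
(cycle-scale noise is approximately normal) with a two-tailed Student's
t-test; p-values map onto the conventional star categories
(* p<0.05, ** p<0.01, *** p<0.001).

Primer amplification efficiency E comes from a dilution series: an
ordinary least-squares line Ct = slope*log10(concentration) + intercept
gives E = 10^(-1/slope) - 1, so a perfect doubling per cycle (slope
-1/log10(2) ~ -3.32) yields E = 1.0 (100%).  E is reported for quality
control but never used to correct the fold changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "CtDataset",
    "ExpressionRow",
    "StandardCurve",
    "TTestResult",
    "primer_efficiency",
    "delta_ct",
    "ddct",
    "ttest_expression",
    "expression_table",
    "star_from_p",
]

WELL_COLUMNS = ["gene", "sample", "condition", "replicate", "Ct"]


@dataclass
class CtDataset:
    """Replicate Ct values by gene x sample, plus the analysis design.

    ``wells`` is a long-format DataFrame with columns gene, sample,
    condition, replicate, Ct.  ``reference_gene`` (housekeeping) and
    ``calibrator_sample`` are configuration and may be attached after
    loading via :meth:`with_design`.
    """

    wells: pd.DataFrame
    reference_gene: Optional[str] = None
    calibrator_sample: Optional[str] = None

    def __post_init__(self):
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"wells table missing columns {missing}")
        ct = self.wells["Ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("all Ct values must be finite")
        if np.any(ct <= 0):
            raise ValueError("all Ct values must be positive cycles")

    def with_design(self, reference_gene: str, calibrator_sample: str) -> "CtDataset":
        return replace(
            self, reference_gene=reference_gene, calibrator_sample=calibrator_sample
        )

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.wells["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.wells["sample"]))

    def ct_values(self, gene: str, sample: str) -> np.ndarray:
        rows = self.wells[(self.wells["gene"] == gene) & (self.wells["sample"] == sample)]
        rows = rows.sort_values("replicate")
        return rows["Ct"].to_numpy(dtype=float)

    def condition_of(self, sample: str) -> str:
        rows = self.wells[self.wells["sample"] == sample]
        return rows["condition"].iloc[0] if len(rows) else ""


@dataclass(frozen=True)
class ExpressionRow:
    gene: str
    sample: str
    condition: str
    n_replicates: int
    mean_dct: float
    sd_dct: float
    fold_change: float
    p_value: float
    star: str


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    star: str
    degenerate_variance: bool = False


@dataclass(frozen=True)
class StandardCurve:
    points: tuple[tuple[float, float], ...]  # (log10 concentration, Ct)
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def star_from_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def primer_efficiency(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a dilution series and report amplification efficiency.

    ``points`` are (log10 concentration, Ct) pairs from at least three
    distinct concentrations.  A non-negative slope cannot arise from a
    valid dilution series; it triggers a warning and E is reported NaN.
    """
    points = tuple((float(a), float(b)) for a, b in points)
    log_conc = np.array([p[0] for p in points])
    ct = np.array([p[1] for p in points])
    if len(set(log_conc.tolist())) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    fit = sp_stats.linregress(log_conc, ct)
    if fit.slope >= 0:
        warnings.warn(
            f"standard-curve slope {fit.slope:.3f} is non-negative; "
            "efficiency is not interpretable",
            stacklevel=2,
        )
        efficiency = math.nan
    else:
        efficiency = 10 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        points=points,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def delta_ct(data: CtDataset, gene: str, sample: str, paired: bool = True) -> np.ndarray:
    """Per-replicate dCt = Ct_target - Ct_reference for one sample.

    ``paired`` matches replicate i of the target with replicate i of the
    reference; unpaired subtracts the reference mean instead.
    """
    if data.reference_gene is None:
        raise ValueError("dataset has no reference gene; call with_design() first")
    target = data.ct_values(gene, sample)
    reference = data.ct_values(data.reference_gene, sample)
    if target.size == 0:
        raise ValueError(f"no Ct wells for gene {gene!r} in sample {sample!r}")
    if reference.size == 0:
        raise ValueError(
            f"reference gene {data.reference_gene!r} missing in sample {sample!r}"
        )
    if paired:
        if target.size != reference.size:
            raise ValueError(
                f"cannot pair {target.size} target with {reference.size} reference "
                f"replicates in sample {sample!r}; use paired=False"
            )
        return target - reference
    return target - reference.mean()


def ddct(data: CtDataset, gene: str, paired: bool = True) -> list[ExpressionRow]:
    """Fold change of one gene in every sample, relative to the calibrator.

    Returns one row per sample with mean/sd of dCt, 2^-ddCt, and the
    t-test against the calibrator sample (the calibrator itself gets
    p = 1, ns, fold exactly 1).
    """
    if data.calibrator_sample is None:
        raise ValueError("dataset has no calibrator sample; call with_design() first")
    calibrator = data.calibrator_sample
    samples = [s for s in data.samples if data.ct_values(gene, s).size]
    if calibrator not in samples:
        raise ValueError(f"gene {gene!r} has no wells in calibrator sample {calibrator!r}")
    cal_dct = delta_ct(data, gene, calibrator, paired=paired)
    rows = []
    for sample in samples:
        dct = delta_ct(data, gene, sample, paired=paired)
        ddct_value = dct.mean() - cal_dct.mean()
        fold = 2.0 ** (-ddct_value)
        if sample == calibrator:
            p, star = 1.0, "ns"
        else:
            test = ttest_expression(data, gene, sample, calibrator, paired=paired)
            p, star = test.p, test.star
        rows.append(
            ExpressionRow(
                gene=gene,
                sample=sample,
                condition=data.condition_of(sample),
                n_replicates=int(dct.size),
                mean_dct=float(dct.mean()),
                sd_dct=float(dct.std(ddof=1)) if dct.size > 1 else 0.0,
                fold_change=float(fold),
                p_value=float(p),
                star=star,
            )
        )
    return rows


def ttest_expression(
    data: CtDataset,
    gene: str,
    sample_a: str,
    sample_b: str,
    equal_var: bool = True,
    paired: bool = True,
) -> TTestResult:
    """Two-sample two-tailed t-test on replicate dCt values.

    Student's (pooled-variance) test by default; ``equal_var=False`` gives
    Welch's. With zero pooled variance the test degenerates: p is 0 when
    the means differ and 1 otherwise, flagged in the result.
    """
    a = delta_ct(data, gene, sample_a, paired=paired)
    b = delta_ct(data, gene, sample_b, paired=paired)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per sample for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, star="ns", degenerate_variance=True)
        return TTestResult(
            t=math.copysign(math.inf, a.mean() - b.mean()),
            p=0.0,
            star="***",
            degenerate_variance=True,
        )
    t, p = sp_stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p), star=star_from_p(float(p)))


def expression_table(data: CtDataset, genes: Optional[Sequence[str]] = None, paired: bool = True) -> pd.DataFrame:
    """Long-format fold-change table over all target genes and samples."""
    if data.reference_gene is None or data.calibrator_sample is None:
        raise ValueError("dataset needs a reference gene and calibrator sample")
    if genes is None:
        genes = [g for g in data.genes if g != data.reference_gene]
    records = []
    for gene in genes:
        for row in ddct(data, gene, paired=paired):
            records.append(row.__dict__)
    return pd.DataFrame.from_records(records)
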
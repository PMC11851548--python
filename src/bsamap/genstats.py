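"""Population and expression statistics for the mapping study.

Chi-square goodness-of-fit for Mendelian segregation ratios, co-segregation
checks under a recessive model, 2^−ΔΔCt relative expression from qPCR cycle
thresholds, two-sample trait comparisons (Student's t), and threshold-based
filtering of a differential-expression results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationResult",
    "QpcrSample",
    "chi_square_gof",
    "cosegregation_check",
    "relative_expression",
    "trait_compare",
    "filter_degs",
]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class QpcrSample:
    """Cycle thresholds for one test sample and its calibrator."""

    ct_target: float
    ct_reference: float
    calibrator_ct_target: float
    calibrator_ct_reference: float

    def __post_init__(self) -> None:
        vals = (self.ct_target, self.ct_reference, self.calibrator_ct_target, self.calibrator_ct_reference)
        if not all(np.isfinite(vals)):
            raise ValueError("Ct values must be finite")


def chi_square_gof(
    observed: Sequence[int],
    ratio: Sequence[float],
    df: int | None = None,
) -> SegregationResult:
    """Pearson chi-square goodness of fit against an expected ratio.

    ``chi2 = Σ (obs − exp)² / exp`` with expected counts ``total × r/Σr``;
    no continuity correction.  ``df`` defaults to the standard classes − 1
    but can be overridden (some reports use a different convention), with
    the p-value taken from the chi-square upper tail at that df.
    """
    obs = np.asarray(observed, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if obs.shape != r.shape:
        raise ValueError(f"observed ({obs.shape}) and ratio ({r.shape}) length mismatch")
    if (obs < 0).any() or obs.sum() <= 0:
        raise ValueError("observed counts must be >= 0 with a positive total")
    if (r <= 0).any():
        raise ValueError("ratio weights must be positive")
    expected = obs.sum() * r / r.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    if df is None:
        df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(x) for x in r),
        expected=tuple(float(x) for x in expected),
        chi2=chi2,
        df=int(df),
        p=p,
    )


def cosegregation_check(
    genotypes: Sequence[int], phenotypes: Sequence[str]
) -> tuple[bool, int]:
    """Concordance of a marker with a recessive phenotype.

    A plant is discordant when its phenotype contradicts the recessive
    model at the marker: mutant ("late") without dosage 2, or normal with
    dosage 2.  Returns (co-segregating, discordant count).
    """
    g = np.asarray(genotypes)
    ph = np.asarray(phenotypes)
    if g.shape != ph.shape:
        raise ValueError("genotype and phenotype lists must have equal length")
    if not np.isin(g, (0, 1, 2)).all():
        bad = sorted(set(g.tolist()) - {0, 1, 2})
        raise ValueError(f"genotype codes outside {{0,1,2}}: {bad}")
    late = ph == "late"
    discordant = int(((late) & (g != 2)).sum() + ((~late) & (g == 2)).sum())
    return discordant == 0, discordant


def relative_expression(sample: QpcrSample) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator.
    """
    ddct = (sample.ct_target - sample.ct_reference) - (
        sample.calibrator_ct_target - sample.calibrator_ct_reference
    )
    return float(2.0 ** (-ddct))


def trait_compare(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-group trait summary with Student's pooled-variance t test.

    Returns means, sample SDs, the absolute mean difference, the t statistic
    and the two-sided p.  Degenerate zero-variance inputs: identical means
    give t = 0, p = 1; differing means give an infinite t, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    diff = a.mean() - b.mean()
    df = na + nb - 2
    if pooled == 0:
        t = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / np.sqrt(pooled * (1 / na + 1 / nb))
        p = float(2 * stats.t.sf(abs(t), df))
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(np.sqrt(sa2)),
        "mean_b": float(b.mean()),
        "sd_b": float(np.sqrt(sb2)),
        "mean_difference": float(abs(diff)),
        "t": float(t),
        "df": int(df),
        "p": float(p),
    }


def filter_degs(
    table: pd.DataFrame, lfc_min: float = 0.5, padj_max: float = 0.05
) -> tuple[list[str], list[str]]:
    """Threshold a differential-expression results table.

    Up: log2fc > lfc_min and padj < padj_max; down: log2fc < −lfc_min and
    padj < padj_max — strict inequalities on both sides.  Expects columns
    ``gene, log2fc, padj``; the test itself is upstream, this only screens
    an existing results table.
    """
    if len(table) == 0:
        return [], []
    padj = table["padj"].to_numpy(dtype=float)
    if not np.isfinite(padj).all() or (padj < 0).any() or (padj > 1).any():
        raise ValueError("padj must be finite and within [0, 1]")
    lfc = table["log2fc"].to_numpy(dtype=float)
    sig = padj < padj_max
    up = table.loc[sig & (lfc > lfc_min), "gene"].tolist()
    down = table.loc[sig & (lfc < -lfc_min), "gene"].tolist()
    return up, down
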
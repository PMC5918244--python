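"""qRT-PCR relative expression by the delta-delta-Cq method.

Quantification cycles (Cq) are inputs; technical replicates are averaged
per gene, the target gene is normalized against the unweighted mean Cq
of the reference genes (delta Cq), biological replicates are averaged,
and expression relative to a calibrator strain is
R = 2^(-delta-delta-Cq).  Primer efficiency is estimated from the OLS
slope of Cq against log10 template amount over a dilution series and
reported for quality control; R itself uses the ideal-doubling form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CQ_COLUMNS = ["strain", "target", "bio_rep", "tech_rep", "cq"]


@dataclass(frozen=True)
class EfficiencyResult:
    primer_pair: str
    slope: float           # Cq per log10(template amount)
    efficiency_pct: float  # 100% = perfect doubling per cycle


@dataclass(frozen=True)
class ExpressionResult:
    strain: str
    r: float
    ci_lo: float
    ci_hi: float
    delta_cq_mean: float
    ddcq: float


def primer_efficiency(series, primer_pair: str = "") -> EfficiencyResult:
    """Amplification efficiency from a dilution series of (dilution_fold, cq).

    A ``dilution_fold`` of d means 1/d of the undiluted template, so the
    regressor is log10(1/d) = -log10(d).  Efficiency (percent) is
    (10^(-1/slope) - 1) * 100; a perfectly doubling primer pair gives
    slope -1/log10(2) = -3.32 and 100%.
    """
    series = list(series)
    folds = np.array([d for d, _ in series], dtype=float)
    cqs = np.array([c for _, c in series], dtype=float)
    if np.unique(folds).size < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    log_amount = -np.log10(folds)
    fit = stats.linregress(log_amount, cqs)
    if fit.slope >= 0:
        raise ValueError(
            f"non-negative slope {fit.slope:.3g}: Cq must increase with dilution"
        )
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return EfficiencyResult(primer_pair=primer_pair, slope=float(fit.slope),
                            efficiency_pct=float(eff))


def _mean_tech(table: pd.DataFrame) -> pd.Series:
    """Collapse technical replicates: mean Cq per (target) within one bio rep."""
    return table.groupby("target")["cq"].mean()


def delta_cq(
    measurements: pd.DataFrame, target: str, ref_genes
) -> float:
    """Delta Cq for one strain and biological replicate.

    Technical replicates are averaged per gene first, then
    dCq = Cq(target) - mean over reference genes of their Cq.
    """
    by_gene = _mean_tech(measurements)
    missing = [g for g in [target, *ref_genes] if g not in by_gene.index]
    if missing:
        raise ValueError(f"missing gene(s) in measurements: {', '.join(missing)}")
    return float(by_gene[target] - by_gene[list(ref_genes)].mean())


def _bio_rep_dcqs(table: pd.DataFrame, target: str, ref_genes) -> np.ndarray:
    return np.array(
        [delta_cq(sub, target, ref_genes) for _, sub in table.groupby("bio_rep")]
    )


def relative_expression(
    strain_table: pd.DataFrame,
    calibrator_table: pd.DataFrame,
    target: str = "citT",
    ref_genes=("16S", "idnT"),
    ci_level: float = 0.95,
) -> ExpressionResult:
    """Relative expression of ``target`` in a strain versus a calibrator.

    ddCq = mean bio-rep dCq(strain) - mean bio-rep dCq(calibrator);
    R = 2^(-ddCq).  The CI is a Welch t-interval on ddCq (combining the
    two bio-rep variances), exponentiated; lower ddCq means higher R, so
    the interval flips on exponentiation.
    """
    s_dcq = _bio_rep_dcqs(strain_table, target, ref_genes)
    c_dcq = _bio_rep_dcqs(calibrator_table, target, ref_genes)
    if s_dcq.size < 2 or c_dcq.size < 2:
        raise ValueError("need >= 2 biological replicates per side")
    ddcq = float(s_dcq.mean() - c_dcq.mean())
    v_s = s_dcq.var(ddof=1) / s_dcq.size
    v_c = c_dcq.var(ddof=1) / c_dcq.size
    se = np.sqrt(v_s + v_c)
    if se == 0:
        half = 0.0
    else:
        df = (v_s + v_c) ** 2 / (
            v_s**2 / (s_dcq.size - 1) + v_c**2 / (c_dcq.size - 1)
        )
        half = stats.t.ppf(0.5 + ci_level / 2, df) * se
    strain = strain_table["strain"].iloc[0] if "strain" in strain_table else ""
    return ExpressionResult(
        strain=str(strain),
        r=float(2.0 ** (-ddcq)),
        ci_lo=float(2.0 ** (-(ddcq + half))),
        ci_hi=float(2.0 ** (-(ddcq - half))),
        delta_cq_mean=float(s_dcq.mean()),
        ddcq=ddcq,
    )


def expression_table(
    cq_table: pd.DataFrame,
    calibrator: str = "REL606",
    target: str = "citT",
    ref_genes=("16S", "idnT"),
) -> pd.DataFrame:
    """Per-strain relative expression versus the calibrator, as a tidy frame.

    Includes the log2 ratio (-ddCq) for fold-change style reporting.  The
    calibrator itself appears with R = 1 exactly.
    """
    cal = cq_table[cq_table["strain"] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator strain {calibrator!r} absent from table")
    rows = []
    for strain, sub in cq_table.groupby("strain", sort=False):
        res = relative_expression(sub, cal, target, ref_genes)
        rows.append(
            {
                "strain": strain, "r": res.r, "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi, "ddcq": res.ddcq,
                "log2_ratio": -res.ddcq, "delta_cq_mean": res.delta_cq_mean,
            }
        )
    return pd.DataFrame(rows)
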
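"""Drug-target two-sample Mendelian randomization with cis-pQTL instruments.

The exposure is a circulating drug-target protein; instruments are cis-pQTLs
selected by four criteria: (a) within a flank (default 500 kb) of the
protein-coding region, (b) genome-wide significant association with the
protein (P < 5e-8), (c) mutually independent after LD clumping (r^2 < 0.001),
and (d) single-SNP F statistic (beta/se)^2 > 10. Instruments are then gated
through a *positive control*: an outcome the drug is known to affect (for a
therapeutic target, the treated disease). Only instruments whose control MR
estimate is nominally significant in the expected direction are carried to
the outcome of interest.

Estimators: a single instrument uses the Wald ratio; multiple instruments
use the five-method suite (fixed-effect IVW, MR-Egger, weighted median,
simple mode, weighted mode) plus Cochran's Q heterogeneity and the Egger
intercept pleiotropy test.

All tables are pandas DataFrames with the canonical summary-statistic
columns ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

SUMMARY_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

#: Complementary base, for palindromic-variant detection.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GeneRegion:
    """Coding-region bounds (1-based, inclusive) plus the cis flank size."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    cis_window_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.cis_window_bp < 0:
            raise ValueError("cis_window_bp must be non-negative")


@dataclass
class MREstimate:
    """One causal-effect estimate on the log-odds (beta) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.beta - 1.96 * self.se), math.exp(self.beta + 1.96 * self.se))


@dataclass
class EggerIntercept:
    value: float
    se: float
    pval: float


@dataclass
class SensitivityReport:
    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: EggerIntercept | None = None


@dataclass
class MRReport:
    """Full pipeline output: instruments, gate outcome, estimates, diagnostics."""

    status: str  # "ok", "instruments_not_validated", "no_instruments"
    instruments: pd.DataFrame
    control_estimate: MREstimate | None = None
    primary_estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    replication_estimates: dict[str, MREstimate] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table with the canonical header."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip().casefold() for c in df.columns]
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns: {sorted(missing)}")
    df = df[list(SUMMARY_COLUMNS)].copy()
    df["chr"] = df["chr"].astype(str)
    for col in ("ea", "oa"):
        df[col] = df[col].astype(str).str.upper()
    validate_summary_stats(df)
    return df


def validate_summary_stats(df: pd.DataFrame) -> None:
    if (df["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive standard errors")
    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        raise ValueError("effect-allele frequencies outside [0, 1]")
    if (df["ea"] == df["oa"]).any():
        raise ValueError("effect and other allele identical for some variants")


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Square pairwise-r^2 matrix with rsID header row and column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    if list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix row and column rsIDs differ")
    return ld


def select_cis_pqtls(
    stats: pd.DataFrame, region: GeneRegion, p_threshold: float = 5e-8
) -> pd.DataFrame:
    """Keep variants inside the cis window with p below the significance cut.

    The window is [start - flank, end + flank] on the region's chromosome,
    boundaries inclusive.
    """
    lo = region.start - region.cis_window_bp
    hi = region.end + region.cis_window_bp
    kept = stats[
        (stats["chr"].astype(str) == str(region.chrom))
        & (stats["pos"] >= lo)
        & (stats["pos"] <= hi)
        & (stats["pval"] < p_threshold)
    ].reset_index(drop=True)
    return kept


def ld_clump(
    candidates: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Greedy LD clumping: most significant first, rsID tie-break.

    A candidate is accepted iff its r^2 with every already-accepted variant
    within ``window_bp`` is below the threshold. A missing LD entry for a
    needed pair is fatal — independence is never assumed.
    """
    if candidates.empty:
        return candidates.copy()
    order = candidates.sort_values(["pval", "snp"], kind="mergesort")
    accepted: list[int] = []
    for idx, row in order.iterrows():
        ok = True
        for j in accepted:
            other = order.loc[j]
            if abs(int(row["pos"]) - int(other["pos"])) > window_bp:
                continue
            try:
                r2 = float(ld.loc[row["snp"], other["snp"]])
            except KeyError:
                raise KeyError(
                    f"LD matrix lacks the pair ({row['snp']}, {other['snp']}); "
                    "cannot assume independence"
                ) from None
            if math.isnan(r2):
                raise KeyError(f"LD r^2 missing for pair ({row['snp']}, {other['snp']})")
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(idx)
    return order.loc[accepted].sort_values(["pos", "snp"]).reset_index(drop=True)


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument strength, (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def add_f_statistics(stats: pd.DataFrame) -> pd.DataFrame:
    out = stats.copy()
    out["f_stat"] = (out["beta"] / out["se"]) ** 2
    return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Straightforward matches pass through; reversed allele labels flip the
    outcome beta (and eaf). Palindromic variants (A/T or C/G) are dropped
    when either study's eaf falls in the ambiguity window, otherwise
    resolved by frequency: if the two eafs disagree about the major allele,
    the outcome is treated as strand-flipped and its beta negated.
    Incompatible allele sets are dropped with the reason recorded.

    Returns one row per retained variant with ``beta_exp, se_exp, beta_out,
    se_out, action`` columns; dropped variants are listed in
    ``result.attrs["dropped"]``.
    """
    lo, hi = palindromic_eaf_window
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    rows, dropped = [], []
    for _, r in merged.iterrows():
        ea_e, oa_e = r["ea_exp"], r["oa_exp"]
        ea_o, oa_o = r["ea_out"], r["oa_out"]
        beta_out, eaf_out = float(r["beta_out"]), float(r["eaf_out"])
        palindromic = _is_palindromic(ea_e, oa_e)

        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "none"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "flipped"
        elif not palindromic and (ea_o, oa_o) == (_COMPLEMENT.get(ea_e), _COMPLEMENT.get(oa_e)):
            action = "none"  # other strand, same orientation
        elif not palindromic and (ea_o, oa_o) == (_COMPLEMENT.get(oa_e), _COMPLEMENT.get(ea_e)):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "flipped"
        else:
            dropped.append((r["snp"], "incompatible_alleles"))
            continue

        if palindromic:
            if lo <= float(r["eaf_exp"]) <= hi or lo <= float(r["eaf_out"]) <= hi:
                dropped.append((r["snp"], "palindromic_ambiguous_eaf"))
                continue
            if (float(r["eaf_exp"]) - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                action = "flipped"

        rows.append(
            {
                "snp": r["snp"],
                "ea": ea_e,
                "oa": oa_e,
                "beta_exp": float(r["beta_exp"]),
                "se_exp": float(r["se_exp"]),
                "eaf_exp": float(r["eaf_exp"]),
                "beta_out": beta_out,
                "se_out": float(r["se_out"]),
                "eaf_out": eaf_out,
                "action": action,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["snp", "ea", "oa", "beta_exp", "se_exp", "eaf_exp", "beta_out", "se_out", "eaf_out", "action"],
    )
    out.attrs["dropped"] = dropped
    return out


def _two_sided_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def _ratio_estimates(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and first-order delta-method SEs."""
    bexp = pairs["beta_exp"].to_numpy(dtype=float)
    if np.any(bexp == 0):
        raise ValueError("exposure beta of zero: Wald ratio undefined")
    theta = pairs["beta_out"].to_numpy(dtype=float) / bexp
    se = pairs["se_out"].to_numpy(dtype=float) / np.abs(bexp)
    return theta, se


def wald_ratio(pair: pd.DataFrame | pd.Series, second_order: bool = False) -> MREstimate:
    """Single-instrument estimate: beta_out / beta_exp.

    The default SE is the first-order delta method se_out/|beta_exp|;
    ``second_order=True`` adds the exposure-uncertainty term.
    """
    row = pair.iloc[0] if isinstance(pair, pd.DataFrame) else pair
    bexp = float(row["beta_exp"])
    if bexp == 0:
        raise ValueError("exposure beta is zero: Wald ratio undefined")
    beta = float(row["beta_out"]) / bexp
    se = float(row["se_out"]) / abs(bexp)
    if second_order:
        se = math.sqrt(
            row["se_out"] ** 2 / bexp**2 + row["beta_out"] ** 2 * row["se_exp"] ** 2 / bexp**4
        )
    return MREstimate("wald_ratio", beta, se, _two_sided_p(beta / se), 1)


def ivw(pairs: pd.DataFrame) -> MREstimate:
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios."""
    if len(pairs) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    theta, se = _ratio_estimates(pairs)
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_ivw = float(math.sqrt(1.0 / np.sum(w)))
    return MREstimate("ivw", beta, se_ivw, _two_sided_p(beta / se_ivw), len(pairs))


def egger(pairs: pd.DataFrame) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Weights 1/se_out^2; slope is the causal estimate, the intercept (with its
    p-value, t distribution on n-2 df) is the directional-pleiotropy test.
    Degenerate designs (constant exposure betas) are refused.
    """
    if len(pairs) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    import statsmodels.api as sm

    x = pairs["beta_exp"].to_numpy(dtype=float)
    y = pairs["beta_out"].to_numpy(dtype=float)
    # orient to positive exposure effects so the intercept has a single sign convention
    flip = np.sign(x)
    flip[flip == 0] = 1.0
    x, y = x * flip, y * flip
    if np.allclose(x, x[0]):
        raise ValueError("exposure betas are constant: Egger slope unidentifiable")
    w = 1.0 / pairs["se_out"].to_numpy(dtype=float) ** 2
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    slope, slope_se = float(model.params[1]), float(model.bse[1])
    inter, inter_se = float(model.params[0]), float(model.bse[0])
    df = len(pairs) - 2
    slope_p = float(2.0 * sps.t.sf(abs(slope / slope_se), df))
    inter_p = float(2.0 * sps.t.sf(abs(inter / inter_se), df))
    return (
        MREstimate("egger", slope, slope_se, slope_p, len(pairs)),
        EggerIntercept(inter, inter_se, inter_p),
    )


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, theta))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator; consistent when >=50% of weight is valid.

    The point estimate interpolates the 50th weighted percentile of the
    per-variant ratios (weights 1/se^2); the SE comes from a parametric
    bootstrap (``n_boot`` draws, seeded).
    """
    if len(pairs) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    theta, se = _ratio_estimates(pairs)
    w = 1.0 / se**2
    beta = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    bexp = pairs["beta_exp"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        be = rng.normal(bexp, pairs["se_exp"].to_numpy(dtype=float))
        bo = rng.normal(pairs["beta_out"].to_numpy(dtype=float), pairs["se_out"].to_numpy(dtype=float))
        be[be == 0] = 1e-300
        th = bo / be
        boots[i] = _weighted_median_point(th, w)
    se_b = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se_b, _two_sided_p(beta / se_b), len(pairs))


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Mode of the weighted kernel-smoothed ratio density (normal kernel)."""
    n = len(theta)
    sd = float(np.std(theta, ddof=1))
    mad = float(sps.median_abs_deviation(theta, scale="normal"))
    s = 0.9 * min(x for x in (sd, mad) if x > 0) * n ** (-1 / 5) if max(sd, mad) > 0 else 0.0
    h = max(1e-8, phi * s)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def _mode_estimate(
    pairs: pd.DataFrame, weighted: bool, phi: float, n_boot: int, seed: int
) -> MREstimate:
    if len(pairs) < 3:
        raise ValueError("mode estimators need >= 3 instruments")
    theta, se = _ratio_estimates(pairs)
    w = 1.0 / se**2 if weighted else np.ones_like(theta)
    if np.allclose(theta, theta[0]):
        beta, se_b = float(theta[0]), float(np.min(se))
        method = "weighted_mode" if weighted else "simple_mode"
        return MREstimate(method, beta, se_b, _two_sided_p(beta / se_b), len(pairs))
    beta = _mode_point(theta, w, phi)
    rng = np.random.default_rng(seed)
    bexp = pairs["beta_exp"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        be = rng.normal(bexp, pairs["se_exp"].to_numpy(dtype=float))
        bo = rng.normal(pairs["beta_out"].to_numpy(dtype=float), pairs["se_out"].to_numpy(dtype=float))
        be[be == 0] = 1e-300
        th = bo / be
        boots[i] = _mode_point(th, w, phi)
    se_b = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se_b, _two_sided_p(beta / se_b), len(pairs))


def simple_mode(pairs: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Unweighted mode-of-ratios estimator (smoothing bandwidth factor phi)."""
    return _mode_estimate(pairs, weighted=False, phi=phi, n_boot=n_boot, seed=seed)


def weighted_mode(pairs: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Inverse-variance-weighted mode-of-ratios estimator."""
    return _mode_estimate(pairs, weighted=True, phi=phi, n_boot=n_boot, seed=seed)


def cochran_q(pairs: pd.DataFrame, ivw_beta: float) -> SensitivityReport:
    """Cochran's Q heterogeneity of per-variant ratios around the IVW estimate."""
    if len(pairs) < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    theta, se = _ratio_estimates(pairs)
    w = 1.0 / se**2
    q = float(np.sum(w * (theta - ivw_beta) ** 2))
    df = len(pairs) - 1
    return SensitivityReport(cochran_q=q, q_df=df, q_pval=float(sps.chi2.sf(q, df)))


@dataclass
class MRConfig:
    """Pipeline knobs; defaults mirror the standard cis-pQTL workflow."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    control_alpha: float = 0.05
    control_direction: int = +1  # expected sign of the control effect
    seed: int = 0
    second_order_wald: bool = False


def _estimate_suite(h: pd.DataFrame, config: MRConfig) -> dict[str, MREstimate]:
    """Wald ratio for one instrument, the five-method suite for several."""
    if len(h) == 1:
        return {"wald_ratio": wald_ratio(h, second_order=config.second_order_wald)}
    out: dict[str, MREstimate] = {"ivw": ivw(h)}
    if len(h) >= 3:
        est, intercept = egger(h)
        est.intercept = intercept  # type: ignore[attr-defined]
        out["egger"] = est
        out["weighted_median"] = weighted_median(h, seed=config.seed)
        out["simple_mode"] = simple_mode(h, seed=config.seed + 1)
        out["weighted_mode"] = weighted_mode(h, seed=config.seed + 2)
    return out


def run_mr_pipeline(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    control_outcome_stats: pd.DataFrame,
    region: GeneRegion,
    ld: pd.DataFrame,
    config: MRConfig | None = None,
    replication_outcome_stats: pd.DataFrame | None = None,
) -> MRReport:
    """Instrument selection -> positive-control gate -> outcome MR.

    Steps: cis/p-value selection, LD clumping, weak-instrument (F) filter,
    harmonization against the control outcome, control MR. Only if the
    control estimate is nominally significant (p < control_alpha) with the
    expected sign does the pipeline estimate the primary (and optional
    replication) outcome, attaching heterogeneity/pleiotropy diagnostics
    when more than one instrument survives.
    """
    config = config or MRConfig()
    log: list[str] = []

    candidates = select_cis_pqtls(exposure_stats, region, config.p_threshold)
    log.append(f"cis window + p<{config.p_threshold:g}: {len(candidates)} candidate pQTLs")
    clumped = ld_clump(candidates, ld, config.r2_threshold, config.clump_window_bp)
    log.append(f"LD clumping r2<{config.r2_threshold:g}: {len(clumped)} kept")
    instruments = add_f_statistics(clumped)
    instruments = instruments[instruments["f_stat"] > config.f_min].reset_index(drop=True)
    log.append(f"F>{config.f_min:g}: {len(instruments)} instruments")

    if instruments.empty:
        return MRReport(status="no_instruments", instruments=instruments, log=log)

    h_control = harmonize(instruments, control_outcome_stats)
    if h_control.empty:
        log.append("no instruments survived harmonization with the control outcome")
        return MRReport(status="no_instruments", instruments=instruments, log=log)
    control_est = (
        wald_ratio(h_control, second_order=config.second_order_wald)
        if len(h_control) == 1
        else ivw(h_control)
    )
    validated = (
        control_est.pval < config.control_alpha
        and math.copysign(1.0, control_est.beta) == config.control_direction
    )
    log.append(
        f"positive control: beta={control_est.beta:.4g} p={control_est.pval:.3g} "
        f"({'validated' if validated else 'NOT validated'})"
    )
    if not validated:
        return MRReport(
            status="instruments_not_validated",
            instruments=instruments,
            control_estimate=control_est,
            log=log,
        )

    h_primary = harmonize(instruments, outcome_stats)
    if h_primary.empty:
        log.append("no instruments survived harmonization with the primary outcome")
        return MRReport(
            status="no_instruments", instruments=instruments, control_estimate=control_est, log=log
        )
    primary = _estimate_suite(h_primary, config)

    sensitivity = None
    if len(h_primary) >= 2:
        sensitivity = cochran_q(h_primary, primary["ivw"].beta)
        if "egger" in primary:
            sensitivity.egger_intercept = primary["egger"].intercept  # type: ignore[attr-defined]

    replication: dict[str, MREstimate] = {}
    if replication_outcome_stats is not None:
        h_rep = harmonize(instruments, replication_outcome_stats)
        if not h_rep.empty:
            replication = _estimate_suite(h_rep, config)

    return MRReport(
        status="ok",
        instruments=instruments,
        control_estimate=control_est,
        primary_estimates=primary,
        sensitivity=sensitivity,
        replication_estimates=replication,
        log=log,
    )
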
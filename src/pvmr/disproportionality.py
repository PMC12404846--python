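"""Four-algorithm disproportionality analysis over drug-event 2x2 tables.

For a target drug and a target event (a single preferred term or a pooled
SMQ term set), reports are cross-classified case-level into

====  ==========================================
a     target drug and target event
b     target drug, other events
c     other drugs, target event
d     other drugs, other events
====  ==========================================

with N = a+b+c+d. The four signal statistics, with their conventional
decision thresholds:

* ROR (reporting odds ratio) = ad/(bc); 95% CI on the log scale with
  s = sqrt(1/a+1/b+1/c+1/d). Signal: CI lower bound > 1 and a >= 3.
* PRR (proportional reporting ratio) = a(c+d)/(c(a+b)), with the Pearson
  chi-square statistic (no continuity correction). Signal: PRR >= 2,
  chi2 >= 4, a >= 3.
* BCPNN information component IC = log2(a*N/((a+c)(a+b))); its lower
  credible bound IC025 = IC - 2*sqrt(V) with V = (1/a+1/b+1/c+1/d)/ln(2)^2.
  Signal: IC025 > 0.
* MGPS relative reporting ratio EBGM = a*N/((a+c)(a+b)) (identical to 2^IC)
  with lower bound EBGM05 = exp(ln EBGM - z*s), z = 1.64 by default.
  Signal: EBGM05 > 2.

A pair is *positive* when all four criteria fire (configurable to "any").
No multiple-testing adjustment is applied across events: thresholds operate
per pair, as is conventional in spontaneous-report screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pvmr.faers_io import CleanCaseSet, normalize_term
from pvmr.smq_mapping import AKI_SMQ_NARROW, CKD_SMQ_NARROW, SMQDictionary, classify_pt

#: Default one-sided z for the EBGM lower bound. 1.64 is the convention used
#: in much of the FAERS-mining literature (and what reproduces published
#: EBGM05 values); pass z05=1.645 or 1.96 for stricter bounds.
DEFAULT_Z05 = 1.64

LN2_SQ = math.log(2.0) ** 2

AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<18", -math.inf, 18.0),
    ("18-59", 18.0, 60.0),
    ("60-69", 60.0, 70.0),
    ("70-79", 70.0, 80.0),
    (">=80", 80.0, math.inf),
)
WEIGHT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<40", -math.inf, 40.0),
    ("40-59", 40.0, 60.0),
    ("60-79", 60.0, 80.0),
    ("80-99", 80.0, 100.0),
    (">=100", 100.0, math.inf),
)
# Age-unit codes to years (FAERS AGE_COD).
_AGE_UNIT_YEARS = {"DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0}


@dataclass(frozen=True)
class ContingencyTable:
    """Case-level 2x2 counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalStatistics:
    """The four disproportionality statistics for one table.

    Fields are NaN when undefined (zero cell / margin); the reason is kept in
    ``undefined`` keyed by statistic name, so downstream code never has to
    interpret a silent infinity.
    """

    ror: float = math.nan
    ror_ci95: tuple[float, float] = (math.nan, math.nan)
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    e_ic: float = math.nan
    v_ic: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    undefined: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class SignalThresholds:
    """Decision rules; defaults follow the conventional four-algorithm criteria."""

    min_a: int = 3
    ror_ci_lower_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    combination: str = "all"  # "all" (every algorithm fires) or "any"

    def __post_init__(self) -> None:
        if self.combination not in ("all", "any"):
            raise ValueError(f"combination must be 'all' or 'any', got {self.combination!r}")


@dataclass
class SignalDecision:
    drug: str
    pt: str
    table: ContingencyTable
    stats: SignalStatistics
    flags: dict[str, bool]
    evaluable: bool
    positive: bool
    scope: frozenset[str] = frozenset()


def _log_se(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def compute_ror(t: ContingencyTable) -> SignalStatistics:
    """Reporting odds ratio with 95% Wald CI on the log scale."""
    out = SignalStatistics()
    if min(t.a, t.b, t.c, t.d) == 0:
        out.undefined["ror"] = "zero cell: ROR and its CI are undefined"
        return out
    ror = (t.a * t.d) / (t.b * t.c)
    s = _log_se(t)
    out.ror = ror
    out.ror_ci95 = (math.exp(math.log(ror) - 1.96 * s), math.exp(math.log(ror) + 1.96 * s))
    return out


def compute_prr(t: ContingencyTable) -> SignalStatistics:
    """Proportional reporting ratio and Pearson chi-square (no correction)."""
    out = SignalStatistics()
    if t.c == 0 or (t.a + t.b) == 0:
        out.undefined["prr"] = "zero margin: PRR undefined"
        return out
    out.prr = t.a * (t.c + t.d) / (t.c * (t.a + t.b))
    margins = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if margins == 0:
        out.undefined["chi2"] = "zero margin: chi-square undefined"
    else:
        out.chi2 = (t.a * t.d - t.b * t.c) ** 2 * t.N / margins
    return out


def compute_bcpnn(t: ContingencyTable) -> SignalStatistics:
    """Information component IC and its lower credible bound IC025.

    IC = log2 of the relative reporting ratio; IC025 = IC - 2*sqrt(V) with
    V = (1/a+1/b+1/c+1/d)/ln(2)^2, the log2-scale delta-method variance.
    """
    out = SignalStatistics()
    if t.a == 0 or (t.a + t.b) == 0 or (t.a + t.c) == 0:
        out.undefined["ic"] = "a = 0 or zero margin: IC undefined"
        return out
    rrr = t.a * t.N / ((t.a + t.c) * (t.a + t.b))
    out.ic = out.e_ic = math.log2(rrr)
    if min(t.b, t.c, t.d) == 0:
        out.undefined["ic025"] = "zero cell: IC variance undefined"
        return out
    out.v_ic = (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) / LN2_SQ
    out.ic025 = out.ic - 2.0 * math.sqrt(out.v_ic)
    return out


def compute_mgps(t: ContingencyTable, z05: float = DEFAULT_Z05) -> SignalStatistics:
    """Relative reporting ratio EBGM and its one-sided lower bound EBGM05."""
    out = SignalStatistics()
    if (t.a + t.b) == 0 or (t.a + t.c) == 0:
        out.undefined["ebgm"] = "zero margin: EBGM undefined"
        return out
    out.ebgm = t.a * t.N / ((t.a + t.c) * (t.a + t.b))
    if min(t.a, t.b, t.c, t.d) == 0:
        out.undefined["ebgm05"] = "zero cell: EBGM05 undefined"
        return out
    out.ebgm05 = math.exp(math.log(out.ebgm) - z05 * _log_se(t))
    return out


def compute_statistics(t: ContingencyTable, z05: float = DEFAULT_Z05) -> SignalStatistics:
    """All four algorithms on one table; NaN + reason where undefined."""
    ror, prr, bcp, mgp = compute_ror(t), compute_prr(t), compute_bcpnn(t), compute_mgps(t, z05)
    return SignalStatistics(
        ror=ror.ror,
        ror_ci95=ror.ror_ci95,
        prr=prr.prr,
        chi2=prr.chi2,
        ic=bcp.ic,
        ic025=bcp.ic025,
        e_ic=bcp.e_ic,
        v_ic=bcp.v_ic,
        ebgm=mgp.ebgm,
        ebgm05=mgp.ebgm05,
        undefined={**ror.undefined, **prr.undefined, **bcp.undefined, **mgp.undefined},
    )


def evaluate_signal(
    stats: SignalStatistics,
    t: ContingencyTable,
    thresholds: SignalThresholds | None = None,
    drug: str = "",
    pt: str = "",
    scope: frozenset[str] = frozenset(),
) -> SignalDecision:
    """Apply the per-algorithm criteria and the combination rule.

    A pair is evaluable only with a >= min_a (default 3); undefined
    statistics never fire their criterion.
    """
    thr = thresholds or SignalThresholds()
    evaluable = t.a >= thr.min_a

    def ok(x: float) -> bool:
        return isinstance(x, float) and not math.isnan(x)

    flags = {
        "ror": evaluable and ok(stats.ror_ci95[0]) and stats.ror_ci95[0] > thr.ror_ci_lower_gt,
        "prr": evaluable
        and ok(stats.prr)
        and ok(stats.chi2)
        and stats.prr >= thr.prr_min
        and stats.chi2 >= thr.chi2_min,
        "bcpnn": ok(stats.ic025) and stats.ic025 > thr.ic025_gt,
        "mgps": ok(stats.ebgm05) and stats.ebgm05 > thr.ebgm05_gt,
    }
    combined = all(flags.values()) if thr.combination == "all" else any(flags.values())
    return SignalDecision(
        drug=drug,
        pt=pt,
        table=t,
        stats=stats,
        flags=flags,
        evaluable=evaluable,
        positive=evaluable and combined,
        scope=scope,
    )


def _case_pt_frame(case_set: CleanCaseSet) -> pd.DataFrame:
    """Unique (primaryid, normalized pt) pairs — the case-level counting unit."""
    cases = case_set.cases
    if cases.empty:
        return pd.DataFrame(columns=["primaryid", "pt"])
    pids, pts = [], []
    for pid, s in zip(cases["primaryid"], cases["pts"]):
        for pt in s:
            pids.append(pid)
            pts.append(pt)
    return pd.DataFrame({"primaryid": pids, "pt": pts})


def build_contingency(
    drug_cases: CleanCaseSet, background: CleanCaseSet, pt_group: set[str] | frozenset[str]
) -> ContingencyTable:
    """Case-level 2x2 counts for a drug against a PT or pooled PT set.

    ``background`` must hold the *other-drug* cases only (same quarter range);
    overlapping primaryids between the two sets would double-count and are
    fatal. A case counts once per cell no matter how many of its PTs fall in
    the group.
    """
    if not pt_group:
        raise ValueError("pt_group must contain at least one preferred term")
    overlap = drug_cases.primaryids & background.primaryids
    if overlap:
        raise ValueError(
            f"{len(overlap)} primaryids occur in both drug cases and background; "
            "background must exclude the target drug's cases"
        )
    group = {normalize_term(p) for p in pt_group}

    def _count_hits(cs: CleanCaseSet) -> int:
        return int(sum(1 for s in cs.cases["pts"] if not group.isdisjoint(s)))

    a = _count_hits(drug_cases)
    c = _count_hits(background)
    return ContingencyTable(a=a, b=len(drug_cases) - a, c=c, d=len(background) - c)


def screen(
    drug_cases: CleanCaseSet,
    background: CleanCaseSet,
    dictionary: SMQDictionary,
    thresholds: SignalThresholds | None = None,
    drug_name: str = "",
    include_smq_groups: bool = True,
    z05: float = DEFAULT_Z05,
) -> list[SignalDecision]:
    """Evaluate every PT observed for the drug, plus pooled SMQ groups.

    Returns decisions sorted with positives first (descending ROR), then the
    rest alphabetically by PT.
    """
    thr = thresholds or SignalThresholds()
    decisions: list[SignalDecision] = []
    if len(drug_cases) == 0:
        return decisions

    drug_pairs = _case_pt_frame(drug_cases)
    bg_pairs = _case_pt_frame(background)
    n_drug, n_bg = len(drug_cases), len(background)
    a_counts = drug_pairs.groupby("pt")["primaryid"].nunique()
    c_counts = bg_pairs.groupby("pt")["primaryid"].nunique()

    display = {}
    for s in drug_cases.cases["pts_display"]:
        for pt in s:
            display.setdefault(normalize_term(pt), pt)

    for pt_norm, a in a_counts.items():
        a = int(a)
        c = int(c_counts.get(pt_norm, 0))
        t = ContingencyTable(a=a, b=n_drug - a, c=c, d=n_bg - c)
        decisions.append(
            evaluate_signal(
                compute_statistics(t, z05),
                t,
                thr,
                drug=drug_name,
                pt=display.get(pt_norm, pt_norm),
                scope=classify_pt(pt_norm, dictionary),
            )
        )

    if include_smq_groups:
        for label, scope in (("AKI (SMQ narrow)", AKI_SMQ_NARROW), ("CKD (SMQ narrow)", CKD_SMQ_NARROW)):
            group = dictionary.scope_pts(scope)
            if not group:
                continue
            t = build_contingency(drug_cases, background, group)
            decisions.append(
                evaluate_signal(
                    compute_statistics(t, z05), t, thr, drug=drug_name, pt=label, scope=frozenset({scope})
                )
            )

    def sort_key(d: SignalDecision):
        ror = d.stats.ror if not math.isnan(d.stats.ror) else -math.inf
        return (0, -ror, d.pt) if d.positive else (1, 0.0, d.pt)

    return sorted(decisions, key=sort_key)


def screen_snapshot(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    target_names: set[str] | list[str],
    dictionary: SMQDictionary,
    thresholds: SignalThresholds | None = None,
    drug_name: str | None = None,
    z05: float = DEFAULT_Z05,
) -> tuple[list[SignalDecision], CleanCaseSet, CleanCaseSet]:
    """Clean a snapshot, split target vs all-other-drug background, and screen.

    The background comparator is every cleaned case in the snapshot that is
    not a target-drug case, so the 2x2 margins cover the drug's own
    reporting window. Returns (decisions, target case set, background case
    set).
    """
    from pvmr.faers_io import assemble_case_set

    target = assemble_case_set(demo, drug, reac, set(target_names))
    everyone = assemble_case_set(demo, drug, reac, None)
    bg_cases = everyone.cases[~everyone.cases["primaryid"].isin(target.primaryids)]
    background = CleanCaseSet(
        cases=bg_cases.reset_index(drop=True),
        provenance=everyone.provenance,
        quarter_range=everyone.quarter_range,
    )
    name = drug_name if drug_name is not None else "/".join(sorted(set(target_names)))
    decisions = screen(target, background, dictionary, thresholds, drug_name=name, z05=z05)
    return decisions, target, background


def decisions_frame(decisions: list[SignalDecision]) -> pd.DataFrame:
    """Flatten decisions into the fixed-column export table."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "drug": d.drug,
                "pt": d.pt,
                "scope": ";".join(sorted(d.scope)),
                "a": d.table.a,
                "b": d.table.b,
                "c": d.table.c,
                "d": d.table.d,
                "ror": d.stats.ror,
                "ror_l": d.stats.ror_ci95[0],
                "ror_u": d.stats.ror_ci95[1],
                "prr": d.stats.prr,
                "chi2": d.stats.chi2,
                "ic": d.stats.ic,
                "ic025": d.stats.ic025,
                "ebgm": d.stats.ebgm,
                "ebgm05": d.stats.ebgm05,
                "flag_ror": d.flags["ror"],
                "flag_prr": d.flags["prr"],
                "flag_bcpnn": d.flags["bcpnn"],
                "flag_mgps": d.flags["mgps"],
                "evaluable": d.evaluable,
                "positive": d.positive,
            }
        )
    columns = [
        "drug", "pt", "scope", "a", "b", "c", "d", "ror", "ror_l", "ror_u", "prr", "chi2",
        "ic", "ic025", "ebgm", "ebgm05", "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps",
        "evaluable", "positive",
    ]
    return pd.DataFrame(rows, columns=columns)


def forest_export(
    decisions: list[SignalDecision], path: str | Path, plot_path: str | Path | None = None
) -> pd.DataFrame:
    """Write the tidy decision table; optionally draw a ROR forest plot.

    The plot shows each PT's ROR with its 95% CI on a log axis, the
    conventional display for spontaneous-report signals.
    """
    df = decisions_frame(decisions)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    if plot_path is not None and len(df):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_df = df.dropna(subset=["ror", "ror_l", "ror_u"])
        fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(plot_df), 4) + 1.2))
        y = np.arange(len(plot_df))[::-1]
        ror = plot_df["ror"].to_numpy()
        ax.errorbar(
            ror, y,
            xerr=[ror - plot_df["ror_l"].to_numpy(), plot_df["ror_u"].to_numpy() - ror],
            fmt="s", color="black", ecolor="gray", capsize=2,
        )
        ax.axvline(1.0, color="firebrick", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(plot_df["drug"] + " / " + plot_df["pt"], fontsize=8)
        ax.set_xscale("log")
        ax.set_xlabel("ROR (95% CI)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def _band(values: pd.Series, bands: tuple[tuple[str, float, float], ...]) -> pd.Series:
    labels = pd.Series("missing", index=values.index, dtype=object)
    for name, lo, hi in bands:
        labels[(values >= lo) & (values < hi)] = name
    return labels


def demographics_summary(case_set: CleanCaseSet) -> pd.DataFrame:
    """Counts and proportions by sex, age band, weight band and occupation.

    Age is converted to years from the FAERS age-unit code; missing values
    are tallied in their own category so proportions always sum to 1 within
    a variable.
    """
    cases = case_set.cases
    n = len(cases)
    out_rows = []

    def add(variable: str, labels: pd.Series, order: list[str]) -> None:
        counts = labels.value_counts()
        for cat in order:
            cnt = int(counts.get(cat, 0))
            if cnt or cat != "missing":
                out_rows.append((variable, cat, cnt, cnt / n if n else math.nan))
        extra = [c for c in counts.index if c not in order]
        for cat in sorted(extra):
            out_rows.append((variable, cat, int(counts[cat]), counts[cat] / n if n else math.nan))

    if n:
        sex = cases["sex"].astype("string").fillna("missing").replace({"": "missing"})
        sex = sex.where(sex.isin(["F", "M"]), "missing")
        add("sex", sex.astype(object), ["F", "M", "missing"])

        unit = cases["age_cod"].astype("string").str.upper().map(_AGE_UNIT_YEARS) if "age_cod" in cases else None
        years = pd.to_numeric(cases.get("age"), errors="coerce")
        if unit is not None:
            years = years * unit.fillna(1.0)
        add("age", _band(years, AGE_BANDS), [b[0] for b in AGE_BANDS] + ["missing"])

        wt = pd.to_numeric(cases.get("wt"), errors="coerce")
        add("weight_kg", _band(wt, WEIGHT_BANDS), [b[0] for b in WEIGHT_BANDS] + ["missing"])

        occ = cases["occp_cod"].astype("string").fillna("missing").replace({"": "missing"})
        add("occupation", occ.astype(object), ["MD", "HP", "PH", "RN", "OT", "missing"])

    return pd.DataFrame(out_rows, columns=["variable", "category", "count", "proportion"])
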
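"""Ground-truth simulators for the two pipeline stages.

``simulate_faers`` produces a FAERS-like snapshot: a multinomial stream of
spontaneous reports over a drug vocabulary and a PT vocabulary, with planted
drug-event reporting-rate ratios, duplicate case versions (exercising both
deduplication tie rules), and reporter-occupation / sex / age / weight
strata. The accompanying manifest carries the configuration and the
analytically expected contingency-cell counts, so tests can compare any
pipeline count against closed-form expectations.

``simulate_gwas_pair`` produces exposure (pQTL), positive-control and
outcome summary statistics directly at the summary level — observed betas
are true betas plus sampling noise at the stated SE — together with a
block-diagonal LD r^2 matrix. Two-sample MR only consumes summary data, so
no individual-level genotypes are needed and runtime stays trivial.

Configs are pydantic models: invalid settings fail loudly with the field
name before anything is generated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from pvmr.mr_engine import GeneRegion

_QUARTER_STARTS = {"Q1": "0101", "Q2": "0401", "Q3": "0701", "Q4": "1001"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def default_pt_vocabulary() -> dict[str, float]:
    """Background PT frequencies: a few renal terms plus common generic AEs.

    Renal terms sit at spontaneous-reporting-plausible background rates
    (0.2-0.5% of reports); the bulk of probability mass goes to generic
    terms so null screens resemble a real all-drug background.
    """
    vocab = {
        "Acute kidney injury": 0.005,
        "Renal failure": 0.003,
        "Chronic kidney disease": 0.004,
        "Renal impairment": 0.003,
        "Dialysis": 0.002,
        "Urinary incontinence": 0.002,
        "Urinary hesitation": 0.002,
        "Kidney enlargement": 0.002,
    }
    generic = [
        "Pyrexia", "Headache", "Nausea", "Fatigue", "Vomiting", "Diarrhoea", "Rash",
        "Dizziness", "Dyspnoea", "Anaemia", "Neutropenia", "Thrombocytopenia",
        "Hypotension", "Hypertension", "Cytokine release syndrome", "Tremor",
        "Confusional state", "Pneumonia", "Sepsis", "Oedema peripheral",
        "Arthralgia", "Myalgia", "Pruritus", "Insomnia", "Constipation",
        "Abdominal pain", "Cough", "Chills", "Tachycardia", "Hypokalaemia",
        "Back pain", "Weight decreased",
    ]
    rest = 1.0 - sum(vocab.values())
    for name in generic:
        vocab[name] = rest / len(generic)
    return vocab


class PlantedSignal(BaseModel):
    """A drug-event pair whose reporting rate is multiplied by ``rate_ratio``."""

    drug: str
    pt: str
    rate_ratio: float = Field(gt=0)


class FaersSimConfig(BaseModel):
    """Study conditions for one synthetic FAERS snapshot."""

    seed: int = 0
    n_drugs: int = Field(default=20, gt=0)
    n_background_reports: int = Field(default=50_000, ge=0)
    target_drug: str = "TARGETDRUG"
    target_drug_reports: int = Field(default=2_000, ge=0)
    pt_vocabulary: dict[str, float] = Field(default_factory=default_pt_vocabulary)
    planted_signals: list[PlantedSignal] = Field(default_factory=list)
    duplicate_fraction: float = Field(default=0.05, ge=0, lt=1)
    occupation_mix: dict[str, float] = Field(
        default_factory=lambda: {"MD": 0.40, "HP": 0.15, "PH": 0.08, "RN": 0.10,
                                 "OT": 0.12, "CN": 0.10, "LW": 0.02, "": 0.03}
    )
    sex_mix: dict[str, float] = Field(default_factory=lambda: {"M": 0.52, "F": 0.43, "": 0.05})
    age_band_mix: dict[str, float] = Field(
        default_factory=lambda: {"<18": 0.05, "18-59": 0.35, "60-69": 0.30, "70-79": 0.20, ">=80": 0.10}
    )
    weight_mean: float = Field(default=74.0, gt=0)
    weight_sd: float = Field(default=15.0, gt=0)
    missing_age_fraction: float = Field(default=0.10, ge=0, lt=1)
    missing_weight_fraction: float = Field(default=0.25, ge=0, lt=1)
    quarters: list[str] = Field(default_factory=lambda: ["2023Q1", "2023Q2", "2023Q3", "2023Q4"])

    @field_validator("pt_vocabulary", "occupation_mix", "sex_mix", "age_band_mix")
    @classmethod
    def _probabilities_sum_to_one(cls, v: dict[str, float], info) -> dict[str, float]:
        total = sum(v.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{info.field_name} probabilities sum to {total}, expected 1")
        if any(p < 0 for p in v.values()):
            raise ValueError(f"{info.field_name} contains negative probabilities")
        return v

    @model_validator(mode="after")
    def _planted_pts_known(self) -> "FaersSimConfig":
        for sig in self.planted_signals:
            if sig.pt not in self.pt_vocabulary:
                raise ValueError(f"planted_signals: PT {sig.pt!r} not in pt_vocabulary")
        return self


_AGE_BAND_RANGES = {"<18": (1, 17), "18-59": (18, 59), "60-69": (60, 69), "70-79": (70, 79), ">=80": (80, 95)}

#: Occupation codes the cleaning step treats as healthcare practitioners.
_HP_CODES = {"MD", "HP", "PH", "RN", "OT"}


@dataclass
class FaersSimResult:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write dialect-conformant ``$``-delimited DEMO/DRUG/REAC + manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demo.to_csv(out / "DEMO.txt", sep="$", index=False)
        self.drug.to_csv(out / "DRUG.txt", sep="$", index=False)
        self.reac.to_csv(out / "REAC.txt", sep="$", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _pt_probs_for_drug(
    config: FaersSimConfig, drug: str, pts: list[str], base: np.ndarray
) -> np.ndarray:
    mult = np.ones_like(base)
    for sig in config.planted_signals:
        if sig.drug == drug:
            mult[pts.index(sig.pt)] = sig.rate_ratio
    p = base * mult
    return p / p.sum()


def simulate_faers(config: FaersSimConfig, out_dir: str | Path | None = None) -> FaersSimResult:
    """Generate one synthetic snapshot; same config + seed → identical output.

    Each logical case is one report: one suspect drug (role PS) and one
    reaction PT drawn from the drug's PT distribution (background
    frequencies, rescaled by any planted rate ratio and renormalized).
    ``duplicate_fraction`` of cases are emitted a second time under the same
    CASEID — half with a later FDA_DT (date rule), half with the same date
    and a higher PRIMARYID (tie rule). The manifest stores expected
    contingency-cell counts for every planted pair after the
    healthcare-reporter filter.
    """
    rng = np.random.default_rng(config.seed)
    pts = list(config.pt_vocabulary)
    base = np.array([config.pt_vocabulary[p] for p in pts], dtype=float)

    drugs = [f"DRUG_{i:03d}" for i in range(1, config.n_drugs + 1)]
    n_bg, n_tg = config.n_background_reports, config.target_drug_reports
    n = n_bg + n_tg
    case_drug = np.array(
        list(rng.choice(drugs, size=n_bg)) + [config.target_drug] * n_tg, dtype=object
    )

    # reaction PT per case, per-drug distribution (planted signals shift it)
    pt_idx = np.empty(n, dtype=int)
    planted_drugs = {s.drug for s in config.planted_signals}
    bg_mask = np.ones(n, dtype=bool)
    bg_mask[n_bg:] = False
    plain_bg = bg_mask & ~np.isin(case_drug, list(planted_drugs))
    pt_idx[plain_bg] = rng.choice(len(pts), size=int(plain_bg.sum()), p=base / base.sum())
    for drug in sorted(planted_drugs - {config.target_drug}):
        m = bg_mask & (case_drug == drug)
        pt_idx[m] = rng.choice(len(pts), size=int(m.sum()), p=_pt_probs_for_drug(config, drug, pts, base))
    p_target = _pt_probs_for_drug(config, config.target_drug, pts, base)
    pt_idx[n_bg:] = rng.choice(len(pts), size=n_tg, p=p_target)

    occ_labels = list(config.occupation_mix)
    occ = rng.choice(occ_labels, size=n, p=[config.occupation_mix[k] for k in occ_labels])
    sex_labels = list(config.sex_mix)
    sex = rng.choice(sex_labels, size=n, p=[config.sex_mix[k] for k in sex_labels])
    band_labels = list(config.age_band_mix)
    bands = rng.choice(band_labels, size=n, p=[config.age_band_mix[k] for k in band_labels])
    lo = np.array([_AGE_BAND_RANGES[b][0] for b in bands])
    hi = np.array([_AGE_BAND_RANGES[b][1] for b in bands])
    age = rng.integers(lo, hi + 1).astype(float)
    age[rng.random(n) < config.missing_age_fraction] = np.nan
    wt = np.round(rng.normal(config.weight_mean, config.weight_sd, size=n).clip(30, 200), 1)
    wt[rng.random(n) < config.missing_weight_fraction] = np.nan

    quarter = rng.choice(config.quarters, size=n)
    day = rng.integers(0, 85, size=n)  # within-quarter offset, stays inside ~3 months
    qdates = pd.to_datetime(
        [q[:4] + _QUARTER_STARTS[q[4:]] for q in quarter], format="%Y%m%d"
    ) + pd.to_timedelta(day, unit="D")
    fda_dt = qdates.strftime("%Y%m%d").astype(str)

    caseid = np.array([f"C{i:08d}" for i in range(1, n + 1)], dtype=object)
    primaryid = np.array([f"{i}1" for i in range(1, n + 1)], dtype=object)  # version suffix 1

    demo = pd.DataFrame(
        {
            "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt, "occp_cod": occ,
            "sex": sex, "age": age, "age_cod": "YR", "wt": wt, "quarter": quarter,
        }
    )
    drug_tab = pd.DataFrame({"primaryid": primaryid, "drug_name": case_drug, "role_cod": "PS"})
    reac = pd.DataFrame({"primaryid": primaryid, "pt": [pts[i] for i in pt_idx]})

    # duplicate case versions: same caseid, higher primaryid; half get a later date
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        dup_rows = rng.choice(n, size=n_dup, replace=False)
        later = rng.random(n_dup) < 0.5
        dup_demo = demo.iloc[dup_rows].copy()
        dup_demo["primaryid"] = [f"{i + 1}2" for i in dup_rows]
        new_dates = pd.to_datetime(dup_demo["fda_dt"], format="%Y%m%d") + pd.to_timedelta(
            np.where(later, 30, 0), unit="D"
        )
        dup_demo["fda_dt"] = new_dates.dt.strftime("%Y%m%d")
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        dup_drug = drug_tab.iloc[dup_rows].copy()
        dup_drug["primaryid"] = dup_demo["primaryid"].to_numpy()
        drug_tab = pd.concat([drug_tab, dup_drug], ignore_index=True)
        dup_reac = reac.iloc[dup_rows].copy()
        dup_reac["primaryid"] = dup_demo["primaryid"].to_numpy()
        reac = pd.concat([reac, dup_reac], ignore_index=True)

    p_hp = sum(config.occupation_mix.get(k, 0.0) for k in _HP_CODES)
    expected = {}
    for sig in config.planted_signals:
        n_drug_reports = n_tg if sig.drug == config.target_drug else n_bg / config.n_drugs
        p_sig = float(
            _pt_probs_for_drug(config, sig.drug, pts, base)[pts.index(sig.pt)]
        )
        expected[f"{sig.drug}|{sig.pt}"] = {
            "expected_a_after_cleaning": n_drug_reports * p_hp * p_sig,
            "pt_prob_in_drug": p_sig,
            "rate_ratio": sig.rate_ratio,
        }
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "n_logical_cases": n,
        "n_duplicate_versions": n_dup,
        "p_healthcare_reporter": p_hp,
        "background_pt_probs": dict(zip(pts, (base / base.sum()).tolist())),
        "planted": expected,
    }

    result = FaersSimResult(demo=demo, drug=drug_tab, reac=reac, manifest=manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result


class GwasSimConfig(BaseModel):
    """Study conditions for one synthetic exposure/control/outcome triplet.

    Defaults emulate a deCODE-scale plasma-protein GWAS (n≈35k) instrumenting
    a single gene region, with biobank-scale binary outcomes: a handful of
    strong independent cis instruments inside LD blocks of correlated
    neighbors, a configurable true causal effect ``theta`` on the primary
    outcome and ``control_effect`` on the positive control, and optional
    directional pleiotropy ``delta``.
    """

    seed: int = 0
    n_snps: int = Field(default=60, gt=0)
    gene_symbol: str = "TNFRSF17"
    chrom: str = "16"
    gene_start: int = 12_058_964
    gene_end: int = 12_061_925
    cis_window_bp: int = Field(default=500_000, ge=0)
    ld_block_size: int = Field(default=6, gt=0)
    r2_within_block: float = Field(default=0.8, ge=0, le=1)
    n_instruments: int = Field(default=10, gt=0)
    instrument_beta: float = 0.15
    se_exp_scale: float = Field(default=0.01, gt=0)
    se_out_scale: float = Field(default=0.02, gt=0)
    se_control_scale: float = Field(default=0.02, gt=0)
    theta: float = 0.0  # true causal effect on the primary outcome
    delta: float = 0.0  # directional pleiotropy on the primary outcome
    control_effect: float = 0.5  # true effect on the positive-control outcome
    n_exp: int = 35_559
    n_out: int = 463_010
    n_control: int = 372_617

    @model_validator(mode="after")
    def _enough_blocks(self) -> "GwasSimConfig":
        n_blocks = -(-self.n_snps // self.ld_block_size)
        if self.n_instruments > n_blocks:
            raise ValueError(
                f"n_instruments={self.n_instruments} exceeds the {n_blocks} LD blocks "
                f"available with n_snps={self.n_snps}, ld_block_size={self.ld_block_size}"
            )
        return self

    def region(self) -> GeneRegion:
        return GeneRegion(self.gene_symbol, self.chrom, self.gene_start, self.gene_end, self.cis_window_bp)


@dataclass
class GwasSimResult:
    exposure: pd.DataFrame
    control: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposure.to_csv(out / "exposure.tsv", sep="\t", index=False)
        self.control.to_csv(out / "control.tsv", sep="\t", index=False)
        self.outcome.to_csv(out / "outcome.tsv", sep="\t", index=False)
        self.ld.to_csv(out / "ld.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _summary_frame(
    snps: list[str], chrom: str, pos: np.ndarray, ea: np.ndarray, oa: np.ndarray,
    eaf: np.ndarray, beta: np.ndarray, se: np.ndarray, n: int,
) -> pd.DataFrame:
    from scipy import stats as sps

    z = beta / se
    return pd.DataFrame(
        {
            "snp": snps, "chr": chrom, "pos": pos, "ea": ea, "oa": oa, "eaf": eaf,
            "beta": beta, "se": se,
            "pval": np.clip(2.0 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
            "n": n,
        }
    )


def simulate_gwas_pair(config: GwasSimConfig, out_dir: str | Path | None = None) -> GwasSimResult:
    """Simulate exposure/control/outcome summary stats plus an LD matrix.

    SNPs sit in consecutive LD blocks (pairwise r^2 = ``r2_within_block``
    inside a block, 0 across). The first ``n_instruments`` blocks carry a
    true instrument at the block head with exposure effect around
    ``instrument_beta``; other SNPs in such a block inherit the attenuated
    effect r*beta (r = sqrt(r^2)), mimicking tagging. True outcome betas are
    ``theta * beta_true + delta``; control betas ``control_effect *
    beta_true``. Observed betas add independent N(0, se) noise — the two
    samples of two-sample MR are independent by construction.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    snps = [f"rs{90_000_000 + 13 * i}" for i in range(m)]
    span = config.gene_end + config.cis_window_bp - (config.gene_start - config.cis_window_bp)
    pos = np.sort(
        rng.choice(np.arange(span - 200) + config.gene_start - config.cis_window_bp + 100, size=m, replace=False)
    )
    alleles = np.array(["A", "C", "G", "T"])
    ea = rng.choice(alleles, size=m)
    # draw a non-identical, non-palindromic partner allele to keep harmonization clean
    oa = np.array([rng.choice([x for x in alleles if x != e and _COMP[e] != x]) for e in ea], dtype=object)
    eaf = rng.uniform(0.05, 0.95, size=m)

    block = np.arange(m) // config.ld_block_size
    r_within = math.sqrt(config.r2_within_block) if config.r2_within_block > 0 else 0.0
    beta_true = np.zeros(m)
    instrument_blocks = np.arange(config.n_instruments)
    is_lead = np.zeros(m, dtype=bool)
    for b in instrument_blocks:
        members = np.where(block == b)[0]
        lead = members[0]
        is_lead[lead] = True
        lead_beta = config.instrument_beta * rng.uniform(0.8, 1.25) * rng.choice([-1.0, 1.0])
        beta_true[lead] = lead_beta
        beta_true[members[1:]] = r_within * lead_beta

    se_exp = config.se_exp_scale * rng.uniform(0.8, 1.2, size=m)
    se_out = config.se_out_scale * rng.uniform(0.8, 1.2, size=m)
    se_ctl = config.se_control_scale * rng.uniform(0.8, 1.2, size=m)
    beta_exp_obs = beta_true + rng.normal(0.0, se_exp)
    beta_out_obs = config.theta * beta_true + config.delta + rng.normal(0.0, se_out)
    beta_ctl_obs = config.control_effect * beta_true + rng.normal(0.0, se_ctl)

    exposure = _summary_frame(snps, config.chrom, pos, ea, oa, eaf, beta_exp_obs, se_exp, config.n_exp)
    outcome = _summary_frame(snps, config.chrom, pos, ea, oa, eaf, beta_out_obs, se_out, config.n_out)
    control = _summary_frame(snps, config.chrom, pos, ea, oa, eaf, beta_ctl_obs, se_ctl, config.n_control)

    ld_vals = np.where(block[:, None] == block[None, :], config.r2_within_block, 0.0)
    np.fill_diagonal(ld_vals, 1.0)
    ld = pd.DataFrame(ld_vals, index=snps, columns=snps)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "theta": config.theta,
        "delta": config.delta,
        "control_effect": config.control_effect,
        "instrument_snps": [s for s, lead in zip(snps, is_lead) if lead],
        "beta_true": dict(zip(snps, beta_true.tolist())),
    }
    result = GwasSimResult(exposure=exposure, control=control, outcome=outcome, ld=ld, manifest=manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result

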
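"""Reading and cleaning FAERS-style quarterly report extracts.

Public FAERS quarterly data ships as ``$``-delimited ASCII tables. Three of
them matter here: DEMO (one row per report version, with demographics and
the FDA receipt date), DRUG (one row per drug mention, with a role code),
and REAC (one row per reported reaction preferred term). Reports are keyed
by PRIMARYID; versions of the same case share a CASEID.

Cleaning follows standard pharmacovigilance practice:

* keep only cases where the drug of interest is the *primary suspect* (PS);
* keep only reports filed by healthcare practitioners
  (MD, HP, PH, RN, OT occupation codes);
* deduplicate case versions — within a CASEID keep the most recent FDA_DT,
  and on a date tie the higher PRIMARYID.

The result is a :class:`CleanCaseSet`: one row per case with its reaction
PT set, plus provenance counts for each removal step.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Healthcare-practitioner occupation codes retained by the reporter filter.
HEALTHCARE_OCCUPATIONS = frozenset({"MD", "HP", "PH", "RN", "OT"})

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
DRUG_ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

_DEMO_COLUMNS = ("primaryid", "caseid", "fda_dt", "occp_cod", "sex", "age", "age_cod", "wt", "quarter")
_DRUG_COLUMNS = ("primaryid", "drug_name", "role_cod")
_REAC_COLUMNS = ("primaryid", "pt")

# Column-name synonyms across FAERS eras (e.g. GNDR_COD pre-2014, SEX after).
_DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case", "case_id"),
    "fda_dt": ("fda_dt", "fda_date"),
    "occp_cod": ("occp_cod", "occp_code", "occupation_cod", "occupation"),
    "sex": ("sex", "gndr_cod", "gender"),
    "age": ("age",),
    "age_cod": ("age_cod", "age_unit"),
    "wt": ("wt", "weight", "weight_kg", "wt_kg"),
    "quarter": ("quarter", "period"),
    "drug_name": ("drugname", "drug_name", "medicinalproduct", "prod_ai"),
    "role_cod": ("role_cod", "role_code", "rolecod"),
    "pt": ("pt", "reac_pt", "preferred_term"),
}


@dataclass
class FaersDialect:
    """Format description for one FAERS-style extract.

    ``column_synonyms`` maps canonical names to accepted header spellings
    (matched case-insensitively); extend it to absorb era drift.
    """

    delimiter: str = "$"
    header: bool = True
    column_synonyms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SYNONYMS)
    )


@dataclass
class QuarterTables:
    """Raw parsed DEMO/DRUG/REAC tables plus parse-warning counters."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    warnings: dict[str, int] = field(default_factory=dict)


@dataclass
class CleanCaseSet:
    """Deduplicated, filtered case-level reports.

    ``cases`` has one row per case: the demographic fields plus a ``pts``
    column holding the (possibly empty) frozenset of normalized reaction
    preferred terms, and ``pts_display`` with original casing.
    ``provenance`` counts rows removed at each cleaning step, in the order
    the filters ran.
    """

    cases: pd.DataFrame
    provenance: dict[str, int]
    quarter_range: tuple[str, str] | None = None

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def primaryids(self) -> set[str]:
        return set(self.cases["primaryid"])

    def case_pt_pairs(self) -> pd.DataFrame:
        """Tidy (primaryid, caseid, pt) table, one row per case-PT pair.

        Cases with no reactions contribute one row with an empty ``pt``.
        """
        rows = []
        for _, row in self.cases.iterrows():
            pts = sorted(row["pts_display"]) if row["pts_display"] else [""]
            for pt in pts:
                rows.append((row["primaryid"], row["caseid"], pt))
        return pd.DataFrame(rows, columns=["primaryid", "caseid", "pt"])

    def write(self, out_dir: str | Path, delimiter: str = "\t") -> None:
        """Serialize as a tidy case-PT table plus a provenance JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.case_pt_pairs().to_csv(out_dir / "case_pt.tsv", sep=delimiter, index=False)
        meta = {"provenance": self.provenance, "quarter_range": self.quarter_range}
        (out_dir / "provenance.json").write_text(json.dumps(meta, indent=2))


class FaersLoadError(RuntimeError):
    """Fatal problem while loading a FAERS-style file (missing key column)."""


def normalize_term(s: str) -> str:
    """Trim, collapse internal whitespace and casefold a free-text term."""
    return re.sub(r"\s+", " ", str(s).strip()).casefold()


def _map_columns(df: pd.DataFrame, wanted: tuple[str, ...], synonyms: dict[str, tuple[str, ...]],
                 path: str | Path) -> pd.DataFrame:
    lower = {str(c).strip().casefold(): c for c in df.columns}
    rename = {}
    for canonical in wanted:
        for alias in synonyms.get(canonical, (canonical,)):
            if alias.casefold() in lower:
                rename[lower[alias.casefold()]] = canonical
                break
    out = df.rename(columns=rename)
    if "primaryid" not in out.columns:
        raise FaersLoadError(f"mandatory column 'primaryid' missing in {path}")
    for canonical in wanted:
        if canonical not in out.columns:
            out[canonical] = pd.NA
    return out[list(wanted)]


def _parse_fda_dt(raw: pd.Series) -> tuple[pd.Series, int]:
    """YYYYMMDD integers; anything that is not a valid calendar date → <NA>."""
    as_str = raw.astype("string").str.strip()
    eight_digits = as_str.str.fullmatch(r"\d{8}").fillna(False)
    parsed = pd.to_datetime(as_str.where(eight_digits), format="%Y%m%d", errors="coerce")
    out = pd.Series(
        np.where(parsed.notna(), as_str, None), index=raw.index, dtype="string"
    ).astype("Int64")
    n_bad = int((parsed.isna() & as_str.notna() & (as_str != "")).sum())
    return out, n_bad


def _read_delimited(path: str | Path, dialect: FaersDialect) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.header else None,
            dtype="string",
            engine="python",
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty FAERS file: %s", path)
        return pd.DataFrame()
    return df


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: FaersDialect | None = None,
) -> QuarterTables:
    """Parse one quarter's DEMO/DRUG/REAC files into normalized tables.

    Column names are mapped case-insensitively through the dialect's synonym
    table; unparseable FDA dates become missing (counted in ``warnings``).
    A file without the ``primaryid`` column raises :class:`FaersLoadError`.
    """
    dialect = dialect or FaersDialect()
    warnings: dict[str, int] = {}

    raw_demo = _read_delimited(demo_path, dialect)
    if raw_demo.empty:
        demo = pd.DataFrame(columns=_DEMO_COLUMNS)
    else:
        demo = _map_columns(raw_demo, _DEMO_COLUMNS, dialect.column_synonyms, demo_path)
        demo["fda_dt"], n_bad = _parse_fda_dt(demo["fda_dt"])
        if n_bad:
            logger.warning("%d unparseable fda_dt values in %s set to missing", n_bad, demo_path)
        warnings["bad_fda_dt"] = n_bad
        demo["occp_cod"] = demo["occp_cod"].astype("string").str.strip().str.upper()
        demo["sex"] = demo["sex"].astype("string").str.strip().str.upper()
        for col in ("age", "wt"):
            demo[col] = pd.to_numeric(demo[col], errors="coerce")

    raw_drug = _read_delimited(drug_path, dialect)
    if raw_drug.empty:
        drug = pd.DataFrame(columns=_DRUG_COLUMNS)
    else:
        drug = _map_columns(raw_drug, _DRUG_COLUMNS, dialect.column_synonyms, drug_path)
        drug["role_cod"] = drug["role_cod"].astype("string").str.strip().str.upper()
        bad_roles = drug["role_cod"].notna() & ~drug["role_cod"].isin(DRUG_ROLE_CODES)
        if bad_roles.any():
            warnings["unknown_role_cod"] = int(bad_roles.sum())
            drug.loc[bad_roles, "role_cod"] = pd.NA

    raw_reac = _read_delimited(reac_path, dialect)
    if raw_reac.empty:
        reac = pd.DataFrame(columns=_REAC_COLUMNS)
    else:
        reac = _map_columns(raw_reac, _REAC_COLUMNS, dialect.column_synonyms, reac_path)
        reac["pt"] = reac["pt"].astype("string").str.replace(r"\s+", " ", regex=True).str.strip()
        empty_pt = reac["pt"].isna() | (reac["pt"] == "")
        if empty_pt.any():
            warnings["empty_pt"] = int(empty_pt.sum())
            reac = reac[~empty_pt]

    return QuarterTables(demo=demo, drug=drug, reac=reac.reset_index(drop=True), warnings=warnings)


def deduplicate_cases(demo: pd.DataFrame) -> pd.DataFrame:
    """One record per CASEID: keep the latest FDA_DT, then the higher PRIMARYID.

    PRIMARYIDs are compared numerically when every version of the case has a
    numeric id, lexicographically otherwise. Missing FDA_DT loses every tie
    (treated as minus infinity). Output is sorted by caseid.
    """
    if demo.empty:
        return demo.copy()
    df = demo.copy()
    df["_fda_key"] = pd.to_numeric(df["fda_dt"], errors="coerce").fillna(-1).astype("int64")
    pid_num = pd.to_numeric(df["primaryid"], errors="coerce")
    all_numeric = pid_num.notna().groupby(df["caseid"]).transform("all")
    df["_pid_num"] = pid_num.where(all_numeric, other=np.nan)
    df["_pid_str"] = df["primaryid"].astype(str)
    df = df.sort_values(
        ["caseid", "_fda_key", "_pid_num", "_pid_str"],
        kind="mergesort",
        na_position="first",
    )
    df = df.drop_duplicates("caseid", keep="last")
    return (
        df.drop(columns=["_fda_key", "_pid_num", "_pid_str"])
        .sort_values("caseid", kind="mergesort")
        .reset_index(drop=True)
    )


def filter_primary_suspect(
    drug: pd.DataFrame,
    target_names: set[str] | frozenset[str] | list[str],
    substring: bool = False,
) -> set[str]:
    """Primaryids with at least one primary-suspect record for a target drug.

    Matching is case-insensitive on whitespace-normalized names; with
    ``substring=True`` a target name occurring inside the free-text drug
    string also matches. An empty target list is refused rather than
    silently matching everything.
    """
    if not target_names:
        raise ValueError("target_names must be non-empty; refusing to match all drugs")
    targets = {normalize_term(t) for t in target_names}
    ps = drug[drug["role_cod"] == "PS"]
    if ps.empty:
        return set()
    names = ps["drug_name"].map(normalize_term)
    if substring:
        mask = names.map(lambda n: any(t in n for t in targets))
    else:
        mask = names.isin(targets)
    return set(ps.loc[mask, "primaryid"])


def filter_reporter_occupation(
    demo: pd.DataFrame, allowed: frozenset[str] | set[str] = HEALTHCARE_OCCUPATIONS
) -> pd.DataFrame:
    """Keep reports filed by healthcare practitioners; missing codes drop out."""
    if demo.empty:
        return demo.copy()
    kept = demo[demo["occp_cod"].isin(allowed)].reset_index(drop=True)
    removed = len(demo) - len(kept)
    if removed:
        logger.info("occupation filter removed %d of %d records", removed, len(demo))
    return kept


def assemble_case_set(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    target_names: set[str] | list[str] | None = None,
    substring: bool = False,
    allowed_occupations: frozenset[str] | set[str] = HEALTHCARE_OCCUPATIONS,
) -> CleanCaseSet:
    """Run the full cleaning cascade and join reaction PT sets per case.

    Filter order: primary-suspect target-drug restriction (skipped when
    ``target_names`` is None, e.g. for the all-drug background), then
    reporter occupation, then deduplication. Provenance counts are recorded
    per step in that order. Cases with no reaction rows are retained with an
    empty PT set (dropping them would bias denominators) and counted.
    """
    provenance: dict[str, int] = {"input_reports": len(demo)}
    current = demo

    if target_names is not None:
        pids = filter_primary_suspect(drug, target_names, substring=substring)
        kept = current[current["primaryid"].isin(pids)].reset_index(drop=True)
        provenance["removed_not_target_ps"] = len(current) - len(kept)
        current = kept

    kept = filter_reporter_occupation(current, allowed_occupations)
    provenance["removed_occupation"] = len(current) - len(kept)
    current = kept

    deduped = deduplicate_cases(current)
    provenance["removed_duplicate"] = len(current) - len(deduped)

    pts_map: dict[str, set[str]] = {}
    disp_map: dict[str, set[str]] = {}
    if not reac.empty:
        for pid, pt in zip(reac["primaryid"], reac["pt"]):
            pts_map.setdefault(pid, set()).add(normalize_term(pt))
            disp_map.setdefault(pid, set()).add(str(pt))

    cases = deduped
    empty = frozenset()
    cases["pts"] = [frozenset(pts_map.get(pid, empty)) for pid in cases["primaryid"]]
    cases["pts_display"] = [frozenset(disp_map.get(pid, empty)) for pid in cases["primaryid"]]
    cases["no_reactions"] = [len(s) == 0 for s in cases["pts"]]
    provenance["cases_no_reactions"] = int(cases["no_reactions"].sum())
    provenance["n_cases"] = len(cases)

    if len(cases) == 0:
        logger.warning("no cases survived cleaning (provenance: %s)", provenance)

    quarters = cases["quarter"].dropna() if "quarter" in cases.columns else pd.Series(dtype="string")
    qrange = (str(quarters.min()), str(quarters.max())) if len(quarters) else None
    return CleanCaseSet(cases=cases.reset_index(drop=True), provenance=provenance, quarter_range=qrange)
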
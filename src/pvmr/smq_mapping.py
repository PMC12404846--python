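"""Mapping reaction preferred terms to renal-injury SMQ / SOC buckets.

A standardized MedDRA query (SMQ) is a curated set of preferred terms (PTs)
describing one clinical syndrome; the *narrow* scope trades sensitivity for
specificity. The bundled dictionary covers the narrow acute-kidney-injury
SMQ (21 PTs) and chronic-kidney-disease SMQ (43 PTs); six PTs (dialysis-type
procedures, azotemia, renal failure) belong to both. A small demo list of
renal/urinary system-organ-class (SOC) PTs is included for the SOC fallback;
it is deliberately incomplete — supply the full SOC PT list for real use.

Matching is exact after normalization (trim, collapse whitespace, casefold),
never fuzzy: FAERS reaction strings are already MedDRA PTs, and fuzzy
matching would inflate signal counts. Near misses at edit distance 1 are
logged for manual review but not matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import pandas as pd

from pvmr.faers_io import normalize_term

logger = logging.getLogger(__name__)

AKI_SMQ_NARROW = "AKI_SMQ_NARROW"
CKD_SMQ_NARROW = "CKD_SMQ_NARROW"
SOC_RENAL_URINARY = "SOC_RENAL_URINARY"
VALID_SCOPES = frozenset({AKI_SMQ_NARROW, CKD_SMQ_NARROW, SOC_RENAL_URINARY})

_BUILTIN = "smq_renal_v26_1.tsv"


@dataclass
class SMQDictionary:
    """PT → scope-label mapping with original casing kept for display."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)
    version_label: str = ""

    def scope_pts(self, scope: str) -> set[str]:
        """Normalized PTs carrying the given scope label."""
        return {pt for pt, scopes in self.entries.items() if scope in scopes}

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for scopes in self.entries.values():
            for s in scopes:
                out[s] = out.get(s, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


def load_smq_dictionary(path: str | Path | None = None) -> SMQDictionary:
    """Load a two-column (pt, scope) dictionary; default is the bundled fixture.

    Duplicate (pt, scope) rows are collapsed with a warning; an unknown scope
    label is fatal. An empty file yields an empty dictionary with a warning.
    """
    if path is None:
        source = files("pvmr.data").joinpath(_BUILTIN)
        label = "renal SMQ narrow fixture (MedDRA 26.1 vocabulary)"
        df = pd.read_csv(source.open("r"), sep="\t", dtype="string")
    else:
        label = str(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype="string")
        except pd.errors.EmptyDataError:
            logger.warning("empty SMQ dictionary file: %s", path)
            return SMQDictionary(version_label=label)

    if df.empty:
        logger.warning("SMQ dictionary has no rows: %s", label)
        return SMQDictionary(version_label=label)

    df.columns = [str(c).strip().casefold() for c in df.columns]
    if not {"pt", "scope"} <= set(df.columns):
        raise ValueError(f"SMQ dictionary needs 'pt' and 'scope' columns, got {list(df.columns)}")

    bad = set(df["scope"].str.strip()) - VALID_SCOPES
    if bad:
        raise ValueError(f"unknown scope label(s) in SMQ dictionary: {sorted(bad)}")

    n_dup = int(df.duplicated(subset=["pt", "scope"]).sum())
    if n_dup:
        logger.warning("collapsed %d duplicate (pt, scope) rows in %s", n_dup, label)

    d = SMQDictionary(version_label=label)
    for pt, scope in zip(df["pt"], df["scope"].str.strip()):
        key = normalize_term(pt)
        d.entries[key] = d.entries.get(key, frozenset()) | {scope}
        d.display.setdefault(key, str(pt).strip())
    return d


def _edit_distance_leq1(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    if len(a) > len(b):
        a, b = b, a
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b)) <= 1
    # one insertion: walk with a single allowed skip in the longer string
    i = j = edits = 0
    while i < len(a) and j < len(b):
        if a[i] == b[j]:
            i += 1
        else:
            edits += 1
            if edits > 1:
                return False
        j += 1
    return True


def classify_pt(pt: str, dictionary: SMQDictionary) -> frozenset[str]:
    """Scope labels for one PT; empty set when unmatched. Pure and total."""
    key = normalize_term(pt)
    hit = dictionary.entries.get(key)
    if hit is not None:
        return hit
    for known in dictionary.entries:
        if _edit_distance_leq1(key, known):
            logger.info("PT %r is a near miss of dictionary PT %r (not matched)", pt, known)
            break
    return frozenset()


def soc_fallback_pts(positive_pts: set[str], dictionary: SMQDictionary) -> set[str]:
    """Positive PTs reportable under the renal/urinary SOC but in neither SMQ.

    Used when a drug has no positive SMQ signal: PTs from the renal/urinary
    system organ class are presented instead. Returns normalized PT strings.
    """
    soc = dictionary.scope_pts(SOC_RENAL_URINARY)
    if not soc:
        logger.warning("no SOC renal/urinary PT list loaded; SOC fallback returns nothing")
        return set()
    smq = dictionary.scope_pts(AKI_SMQ_NARROW) | dictionary.scope_pts(CKD_SMQ_NARROW)
    return {normalize_term(pt) for pt in positive_pts} & soc - smq
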
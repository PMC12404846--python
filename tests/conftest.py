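import numpy as np
import pandas as pd
import pytest

from pvmr import load_smq_dictionary

# Worked-example drug-event tables with their published four-algorithm
# statistics (2 dp). ic025 is only checkable for the a=3 rows, where the
# count-based credible-bound formula applies cleanly; None elsewhere.
GOLDEN_ROWS = [
    # drug, pt, a, b, c, d, ror, ror_l, ror_u, prr, chi2, ebgm, ebgm05, ic, ic025
    ("Tisagenlecleucel", "Urinary hesitation", 3, 15237, 544, 15668261,
     5.67, 1.82, 17.64, 5.67, 11.48, 5.64, 2.18, 2.50, 0.83),
    ("Tisagenlecleucel", "Kidney enlargement", 3, 15237, 243, 15668562,
     12.70, 4.07, 39.64, 12.69, 31.92, 12.55, 4.84, 3.65, 1.97),
    ("Axicabtagene ciloleucel", "Urinary incontinence", 35, 19183, 2116, 15662711,
     13.51, 9.67, 18.87, 13.48, 397.96, 13.28, 10.04, 3.73, None),
    ("Axicabtagene ciloleucel", "Renal tubular necrosis", 14, 19204, 3442, 15661385,
     3.32, 1.96, 5.61, 3.32, 22.55, 3.31, 2.13, 1.73, None),
    ("Brexucabtagene autoleucel", "Urinary incontinence", 8, 2890, 1450, 11168998,
     21.32, 10.63, 42.76, 21.27, 153.68, 21.16, 11.82, 4.40, None),
    ("Lisocabtagene maraleucel", "Urinary incontinence", 6, 802, 1004, 7867633,
     58.63, 26.20, 131.20, 58.20, 335.33, 57.86, 29.49, 5.85, None),
    ("Idecabtagene vicleucel", "Acute kidney injury", 26, 1694, 37016, 8346665,
     3.46, 2.35, 5.10, 3.42, 44.78, 3.42, 2.47, 1.77, None),
    ("Idecabtagene vicleucel", "Urinary incontinence", 4, 1716, 1060, 8382621,
     18.43, 6.90, 49.26, 18.39, 65.55, 18.33, 8.05, 4.20, None),
]


@pytest.fixture(scope="session")
def smq_dict():
    return load_smq_dictionary()


@pytest.fixture
def demo_frame():
    """Factory for DEMO-style frames from (primaryid, caseid, fda_dt, occp) rows."""

    def build(rows, **extra):
        df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt", "occp_cod"])
        df["fda_dt"] = pd.array(
            [pd.NA if pd.isna(v) else int(v) for v in df["fda_dt"]], dtype="Int64"
        )
        for col, default in (
            ("sex", "M"), ("age", 60.0), ("age_cod", "YR"), ("wt", 75.0), ("quarter", "2023Q1"),
        ):
            df[col] = extra.get(col, default)
        return df

    return build


def random_demo(rng: np.random.Generator, n_cases: int = 200, dup_fraction: float = 0.2) -> pd.DataFrame:
    """Random demo table with case versions; occupation constant within a case."""
    occs = rng.choice(["MD", "HP", "PH", "RN", "OT", "CN", "LW"], size=n_cases)
    rows = []
    pid = 1
    for i in range(n_cases):
        caseid = f"C{i:05d}"
        n_versions = 1 + int(rng.random() < dup_fraction) + int(rng.random() < dup_fraction / 2)
        base_date = 20200101 + int(rng.integers(0, 300))
        for v in range(n_versions):
            date = base_date + int(rng.integers(0, 3)) * 100  # some ties, some later
            rows.append((str(pid), caseid, date, occs[i]))
            pid += 1
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt", "occp_cod"])
    df["fda_dt"] = df["fda_dt"].astype("Int64")
    df["sex"] = rng.choice(["F", "M"], size=len(df))
    df["age"] = 50.0
    df["age_cod"] = "YR"
    df["wt"] = 70.0
    df["quarter"] = "2023Q1"
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
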
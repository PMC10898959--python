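"""Build the analysis cohort: MASLD classification, exclusion cascade,
trailing exposure-window averaging and covariate encoding.

MASLD is hepatic steatosis (on ultrasonography) plus at least one of five
cardiometabolic criteria; steatosis with all five criteria definitively
false is cryptogenic steatotic liver disease, which is excluded from the
analysis cohort.  Classification uses three-valued logic: a criterion whose
observed components are all false but which has a missing component is
*unknown*, and a record whose category cannot be decided is UNDETERMINED
(and later excluded as missing key information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "MasldCategory",
    "ExclusionCascade",
    "classify_masld",
    "classify_masld_frame",
    "classify_excess_alcohol",
    "classify_excess_alcohol_frame",
    "apply_exclusions",
    "window_average",
    "window_average_table",
    "encode_covariates",
    "descriptive_table",
    "EXCLUSION_ORDER",
]


class MasldCategory(str, Enum):
    MASLD = "MASLD"
    NO_MASLD = "NO_MASLD"
    CRYPTOGENIC_SLD = "CRYPTOGENIC_SLD"
    UNDETERMINED = "UNDETERMINED"


# three-valued criterion logic encoded as floats: 1 true, 0 false, nan unknown


def _or3(*components: np.ndarray) -> np.ndarray:
    """Three-valued OR: true if any true; unknown if none true but any unknown."""
    comp = np.column_stack(components)
    any_true = np.nanmax(np.where(np.isnan(comp), 0.0, comp), axis=1) > 0
    any_nan = np.isnan(comp).any(axis=1)
    out = np.where(any_true, 1.0, np.where(any_nan, np.nan, 0.0))
    return out


def _cmp(series, op, threshold) -> np.ndarray:
    v = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        res = op(v, threshold).astype(float)
    res[np.isnan(v)] = np.nan
    return res


def _flag(series) -> np.ndarray:
    v = series.to_numpy()
    out = np.empty(len(v), dtype=float)
    for i, x in enumerate(v):
        out[i] = np.nan if pd.isna(x) else float(bool(x))
    return out


def cardiometabolic_criteria(df: pd.DataFrame) -> np.ndarray:
    """(n, 5) array of criteria in {1, 0, nan}.

    1. BMI >= 23 kg/m², or WC > 94 cm (men) / > 80 cm (women)
    2. fasting glucose >= 100 mg/dL, HbA1c >= 5.7 %, diabetes history or
       antidiabetic treatment
    3. SBP >= 130 or DBP >= 85 mmHg, or antihypertensive treatment
    4. TG >= 150 mg/dL or lipid-lowering treatment
    5. HDL <= 40 (men) / <= 50 (women) mg/dL or lipid-lowering treatment
    """
    import operator as _op

    male = (df["sex"] == "male").to_numpy()
    wc = pd.to_numeric(df["wc"], errors="coerce").to_numpy(dtype=float)
    wc_thr = np.where(male, 94.0, 80.0)
    with np.errstate(invalid="ignore"):
        wc_c = (wc > wc_thr).astype(float)
    wc_c[np.isnan(wc)] = np.nan
    c1 = _or3(_cmp(df["bmi"], _op.ge, 23.0), wc_c)
    c2 = _or3(
        _cmp(df["glucose"], _op.ge, 100.0),
        _cmp(df["hba1c"], _op.ge, 5.7),
        _flag(df["hx_diabetes"]),
        _flag(df["antidiabetic_tx"]),
    )
    c3 = _or3(
        _cmp(df["sbp"], _op.ge, 130.0),
        _cmp(df["dbp"], _op.ge, 85.0),
        _flag(df["antihypertensive_tx"]),
    )
    c4 = _or3(_cmp(df["tg"], _op.ge, 150.0), _flag(df["lipid_lowering_tx"]))
    hdl = pd.to_numeric(df["hdl"], errors="coerce").to_numpy(dtype=float)
    hdl_thr = np.where(male, 40.0, 50.0)
    with np.errstate(invalid="ignore"):
        hdl_c = (hdl <= hdl_thr).astype(float)
    hdl_c[np.isnan(hdl)] = np.nan
    c5 = _or3(hdl_c, _flag(df["lipid_lowering_tx"]))
    return np.column_stack([c1, c2, c3, c4, c5])


def classify_masld_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised MASLD category for every row of a participant table."""
    crit = cardiometabolic_criteria(df)
    any_true = np.nanmax(np.where(np.isnan(crit), 0.0, crit), axis=1) > 0
    all_false = np.all(crit == 0.0, axis=1)
    steat = _flag(df["steatosis_on_us"])

    out = np.full(len(df), MasldCategory.UNDETERMINED.value, dtype=object)
    out[steat == 0.0] = MasldCategory.NO_MASLD.value
    out[(steat == 1.0) & any_true] = MasldCategory.MASLD.value
    out[(steat == 1.0) & all_false] = MasldCategory.CRYPTOGENIC_SLD.value
    return pd.Series(out, index=df.index, name="masld_category")


def classify_masld(record: pd.Series | dict) -> MasldCategory:
    """Classify a single checkup record (total function; missingness -> UNDETERMINED)."""
    df = pd.DataFrame([record])
    return MasldCategory(classify_masld_frame(df).iloc[0])


def classify_excess_alcohol_frame(df: pd.DataFrame) -> np.ndarray:
    """Excess alcohol in {1, 0, nan}: >=2 drinks/day on >=3 days/week for >1 year.

    Never-drinkers are false without needing the quantity fields; for the
    rest, any missing component makes the result missing, otherwise the
    conjunction of the three conditions decides.
    """
    import operator as _op

    drinks = _cmp(df["alcohol_drinks_per_day"], _op.ge, 2.0)
    days = _cmp(df["alcohol_days_per_week"], _op.ge, 3.0)
    years = _cmp(df["alcohol_years"], _op.gt, 1.0)
    comp = np.column_stack([drinks, days, years])
    any_nan = np.isnan(comp).any(axis=1)
    out = np.where(any_nan, np.nan, np.all(comp == 1.0, axis=1).astype(float))
    if "alcohol_status" in df:
        never = (df["alcohol_status"] == "never").to_numpy()
        out = np.where(never, 0.0, out)
    return out


def classify_excess_alcohol(record: pd.Series | dict) -> bool | None:
    v = classify_excess_alcohol_frame(pd.DataFrame([record]))[0]
    return None if np.isnan(v) else bool(v)


@dataclass
class ExclusionCascade:
    """Ordered per-rule removal counts; conservation holds by construction."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(c for _, c in self.steps)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [{"rule": r, "n_excluded": c} for r, c in self.steps],
            "n_retained": self.n_retained,
        }


#: Sequential rule order of the enrollment flow.
EXCLUSION_ORDER = (
    "missing_exposure_or_sono",
    "duplicate_record",
    "age_under_18",
    "missing_masld_fields",
    "missing_alcohol",
    "cirrhosis_hcc",
    "hepatitis",
    "excess_alcohol",
    "sono_abnormality",
    "cryptogenic",
)


def apply_exclusions(
    records: pd.DataFrame, exposure_columns: list[str] | None = None
) -> tuple[pd.DataFrame, ExclusionCascade]:
    """Apply the exclusion cascade sequentially; each record is removed at the
    first rule it triggers, so per-rule counts are additive.

    ``exposure_columns`` names columns whose missingness marks unreliable
    exposure (defaults to any column ending in ``_3yr`` that is present).
    The retained frame gains ``masld_category`` and binary ``masld`` columns.
    """
    if records.empty:
        raise ValueError("empty input")
    df = records.copy()
    if exposure_columns is None:
        exposure_columns = [c for c in df.columns if c.endswith("_3yr")]

    cascade = ExclusionCascade(n_input=len(df))

    # 1. missing address / exposure / sonography
    miss = pd.Series(False, index=df.index)
    for c in exposure_columns:
        miss |= df[c].isna()
    if "steatosis_on_us" in df:
        miss |= df["steatosis_on_us"].isna()
    cascade.steps.append(("missing_exposure_or_sono", int(miss.sum())))
    df = df[~miss]

    # 2. deduplicate: keep the earliest checkup per participant
    if "id" in df.columns:
        order = df.sort_values(["id", "checkup_date"], kind="stable")
        first = order.drop_duplicates("id", keep="first")
        n_dup = len(df) - len(first)
        df = first.sort_index()
    else:
        n_dup = 0
    cascade.steps.append(("duplicate_record", n_dup))

    # 3. age < 18
    young = pd.to_numeric(df["age"], errors="coerce") < 18
    cascade.steps.append(("age_under_18", int(young.sum())))
    df = df[~young]

    # 4. missing key information to define MASLD
    cat = classify_masld_frame(df)
    undet = cat == MasldCategory.UNDETERMINED.value
    cascade.steps.append(("missing_masld_fields", int(undet.sum())))
    df, cat = df[~undet], cat[~undet]

    # 5. missing alcohol intake information
    alc = classify_excess_alcohol_frame(df)
    alc_missing = np.isnan(alc)
    cascade.steps.append(("missing_alcohol", int(alc_missing.sum())))
    df, cat, alc = df[~alc_missing], cat[~alc_missing], alc[~alc_missing]

    # 6. liver cirrhosis / hepatocellular carcinoma history
    cirr = df["hx_cirrhosis"].fillna(False).astype(bool) | df["hx_hcc"].fillna(
        False
    ).astype(bool)
    cascade.steps.append(("cirrhosis_hcc", int(cirr.sum())))
    keep = ~cirr.to_numpy()
    df, cat, alc = df[keep], cat[keep], alc[keep]

    # 7. viral or other hepatitis
    hep = df["hx_hepatitis"].fillna(False).astype(bool)
    cascade.steps.append(("hepatitis", int(hep.sum())))
    keep = ~hep.to_numpy()
    df, cat, alc = df[keep], cat[keep], alc[keep]

    # 8. excessive alcohol intake
    excess = alc == 1.0
    cascade.steps.append(("excess_alcohol", int(excess.sum())))
    df, cat = df[~excess], cat[~excess]

    # 9. significant sonographic abnormality
    sono = df["significant_sono_abnormality"].fillna(False).astype(bool)
    cascade.steps.append(("sono_abnormality", int(sono.sum())))
    keep = ~sono.to_numpy()
    df, cat = df[keep], cat[keep]

    # 10. cryptogenic steatotic liver disease
    cryp = cat == MasldCategory.CRYPTOGENIC_SLD.value
    cascade.steps.append(("cryptogenic", int(cryp.sum())))
    df, cat = df[~cryp], cat[~cryp]

    out = df.copy()
    out["masld_category"] = cat
    out["masld"] = (cat == MasldCategory.MASLD.value).astype(int)
    return out, cascade


# ---------------------------------------------------------------------------
# exposure windows


def _month_ordinals(months) -> np.ndarray:
    """Months as integer ordinals (year*12 + month - 1); accepts Period dtype,
    datetimes or 'yyyy-mm' strings."""
    if isinstance(months, pd.PeriodIndex) or isinstance(
        getattr(months, "dtype", None), pd.PeriodDtype
    ):
        pi = pd.PeriodIndex(months)
    else:
        pi = pd.PeriodIndex(pd.to_datetime(months), freq="M")
    return pi.year.to_numpy() * 12 + pi.month.to_numpy() - 1


def window_average(
    series: pd.DataFrame,
    index_date,
    years: int,
    coverage: float = 0.9,
) -> float:
    """Mean of the ``years*12`` calendar months strictly before the index month.

    ``series`` needs columns ``month`` and ``value``.  If fewer than
    ``coverage`` of the window's months are present the exposure is deemed
    missing (returns nan).  The mean is over available months, invariant to
    row order and linear in the values.
    """
    need = years * 12
    idx = pd.Period(pd.Timestamp(index_date), freq="M")
    idx_ord = idx.year * 12 + idx.month - 1
    ords = _month_ordinals(series["month"])
    in_window = (ords >= idx_ord - need) & (ords < idx_ord)
    vals = series.loc[in_window, "value"].to_numpy(dtype=float)
    n_months = pd.unique(ords[in_window]).size
    if n_months < coverage * need:
        return float("nan")
    return float(vals.mean())


def window_average_table(
    exposure: pd.DataFrame,
    participants: pd.DataFrame,
    years: int = 3,
    coverage: float = 0.9,
) -> pd.DataFrame:
    """Trailing-window exposure means for every participant and pollutant.

    Vectorised version of :func:`window_average` over a long exposure table
    (``participant_id, pollutant, month, value``).  Returns a frame indexed
    like ``participants`` with one ``{pollutant}_{years}yr`` column per
    pollutant, nan where coverage is below the completeness rule.
    """
    need = years * 12
    idx_ord = (
        participants["checkup_date"].dt.year.to_numpy() * 12
        + participants["checkup_date"].dt.month.to_numpy()
        - 1
    )
    idx_map = pd.Series(idx_ord, index=participants["id"].to_numpy())

    ords = _month_ordinals(exposure["month"])
    pid = exposure["participant_id"].to_numpy()
    rel = idx_map.reindex(pid).to_numpy() - ords  # 1..need inside the window
    mask = (rel >= 1) & (rel <= need)

    sub = pd.DataFrame(
        {
            "participant_id": pid[mask],
            "pollutant": exposure["pollutant"].to_numpy()[mask],
            "value": exposure["value"].to_numpy(dtype=float)[mask],
        }
    )
    g = sub.groupby(["participant_id", "pollutant"], sort=False)["value"].agg(
        ["mean", "size"]
    )
    g.loc[g["size"] < coverage * need, "mean"] = np.nan
    wide = g["mean"].unstack("pollutant")
    wide = wide.reindex(participants["id"].to_numpy())
    wide.columns = [f"{p}_{years}yr" for p in wide.columns]
    wide.index = participants.index
    return wide


# ---------------------------------------------------------------------------
# covariate encoding

#: Adjustment covariates with their reference levels (dummy coding).
COVARIATE_REFERENCES: dict[str, str] = {
    "sex": "female",
    "marriage": "single",
    "education": "college_or_higher",
    "income": "lt_28k",
    "smoking": "never",
    "alcohol_status": "never",
    "vegetable_intake": "seldom",
    "fruit_intake": "seldom",
    "sugary_drink_intake": "seldom",
    "fried_food_intake": "seldom",
}

#: Categoricals whose missing values become an explicit "unreported" level.
UNREPORTED_AS_LEVEL = ("marriage", "education", "income")


def encode_covariates(
    cohort: pd.DataFrame,
    include_enrollment_year: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-coded adjustment-covariate model matrix and a column dictionary.

    Age enters continuously.  Marriage/education/income missingness becomes
    an explicit ``unreported`` category; other categorical missingness is
    imputed to the modal category.  Hypertension, diabetes and dyslipidemia
    are deliberately absent: they are part of the outcome definition.
    Enrollment year is categorical (earliest year as reference).
    """
    cols: dict[str, pd.Series] = {}
    coldoc: dict[str, str] = {}
    age = pd.to_numeric(cohort["age"], errors="coerce")
    cols["age"] = age
    coldoc["age"] = "age in years, continuous"

    for var, ref in COVARIATE_REFERENCES.items():
        if var not in cohort:
            continue
        s = cohort[var].astype(object)
        if var in UNREPORTED_AS_LEVEL:
            s = s.where(~pd.isna(s), "unreported")
        else:
            if s.isna().any():
                mode = s.mode(dropna=True)
                if mode.empty:
                    raise ValueError(f"covariate {var} is entirely missing")
                s = s.fillna(mode.iloc[0])
        for level in sorted(set(s.unique()) - {ref}, key=str):
            name = f"{var}_{level}"
            cols[name] = (s == level).astype(float)
            coldoc[name] = f"{var} == {level} (reference: {ref})"

    if "regular_exercise" in cohort:
        s = cohort["regular_exercise"]
        if s.isna().any():
            s = s.fillna(s.mode(dropna=True).iloc[0])
        cols["regular_exercise"] = s.astype(float)
        coldoc["regular_exercise"] = "regular exercise (reference: no)"

    if include_enrollment_year and "enrollment_year" in cohort:
        yrs = pd.to_numeric(cohort["enrollment_year"], errors="coerce").astype(int)
        ref_year = int(yrs.min())
        for y in sorted(yrs.unique()):
            if y == ref_year:
                continue
            name = f"enrollment_year_{y}"
            cols[name] = (yrs == y).astype(float)
            coldoc[name] = f"enrolled in {y} (reference: {ref_year})"

    X = pd.DataFrame(cols, index=cohort.index)
    return X, coldoc


# ---------------------------------------------------------------------------
# descriptive summaries

_CONTINUOUS_SUMMARY = (
    "age", "bmi", "wc", "sbp", "dbp", "tg", "hdl", "ldl", "cholesterol", "alt",
    "pm25_3yr", "pm10_3yr", "co_3yr", "o3_3yr", "so2_3yr", "no2_3yr",
)
_CATEGORICAL_SUMMARY = (
    "sex", "marriage", "education", "income", "smoking", "alcohol_status",
    "vegetable_intake", "fruit_intake", "sugary_drink_intake",
    "fried_food_intake", "regular_exercise",
)


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Stratified summary (mean ± SD for continuous, n (%) for categorical)
    comparing participants with and without MASLD."""
    if "masld" not in cohort:
        raise ValueError("cohort must carry a binary 'masld' column")
    rows = []
    for stratum, sub in (
        ("NO_MASLD", cohort[cohort["masld"] == 0]),
        ("MASLD", cohort[cohort["masld"] == 1]),
    ):
        for var in _CONTINUOUS_SUMMARY:
            if var not in sub:
                continue
            v = pd.to_numeric(sub[var], errors="coerce")
            rows.append(
                {
                    "variable": var, "level": "", "stratum": stratum,
                    "n": int(v.notna().sum()),
                    "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                    "percent": np.nan,
                }
            )
        for var in _CATEGORICAL_SUMMARY:
            if var not in sub:
                continue
            s = sub[var].astype(object).where(~pd.isna(sub[var]), "unreported")
            counts = s.value_counts()
            for level, cnt in counts.items():
                rows.append(
                    {
                        "variable": var, "level": str(level), "stratum": stratum,
                        "n": int(cnt),
                        "mean": np.nan, "sd": np.nan,
                        "percent": 100.0 * cnt / len(sub),
                    }
                )
    return pd.DataFrame(rows)
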
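"""Analysis-sample assembly: outcome filters, covariates, group rules.

Two samples are analyzed: height-for-age z-scores of children aged 12-59
months at the interview (children under 12 months have not lived through the
risk period; |z| > 6 is implausible), and school attendance of 7-16
year-olds. Each filtering step logs its exclusion count so that
``input = retained + sum(per-rule exclusions)`` reconciles exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FE_LEVELS = ("sibling", "neighborhood", "survey")

#: covariates used at every fixed-effects level
CHILD_COVARIATES = ["age_months", "age_months_sq", "birth_order",
                    "preceding_interval_months", "firstborn", "female", "twin"]
#: additional mother-level covariates identified only without sibling FE
MOTHER_COVARIATES = ["mother_education_years", "mother_age_at_birth",
                     "mother_age_at_birth_sq", "number_of_siblings"]


def _ledger(rules: list[tuple[str, int]]) -> pd.DataFrame:
    return pd.DataFrame(rules, columns=["rule", "count"])


def filter_haz_sample(children: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Height-for-age sample: survivors 12-59 months old with plausible z.

    Drops, in order: missing z-score, implausible |z| > 6, age under 12
    months, and children without a linked valid exposure. Returns the sample
    and an exclusion ledger.
    """
    df = children
    rules = []
    n0 = len(df)
    df = df[df["haz"].notna()]
    rules.append(("missing_haz", n0 - len(df)))
    n0 = len(df)
    df = df[df["haz"].abs() <= 6.0]
    rules.append(("implausible_haz", n0 - len(df)))
    n0 = len(df)
    df = df[df["age_months"] >= 12]
    rules.append(("under_12_months", n0 - len(df)))
    n0 = len(df)
    df = df[df["age_months"] <= 59]
    rules.append(("over_59_months", n0 - len(df)))
    n0 = len(df)
    df = df[~df["excluded"].astype(bool) & df["exposure"].notna()]
    rules.append(("no_valid_exposure", n0 - len(df)))
    df = df.copy()
    df["outcome"] = df["haz"].astype(float)
    return df, _ledger(rules)


def filter_school_sample(children: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """School-attendance sample: survivors aged 7-16 years at the interview."""
    df = children
    rules = []
    n0 = len(df)
    df = df[df["school"].notna()]
    rules.append(("missing_school", n0 - len(df)))
    n0 = len(df)
    df = df[(df["age_months"] >= 84) & (df["age_months"] <= 203)]
    rules.append(("outside_7_16_years", n0 - len(df)))
    n0 = len(df)
    df = df[~df["excluded"].astype(bool) & df["exposure"].notna()]
    rules.append(("no_valid_exposure", n0 - len(df)))
    df = df.copy()
    df["outcome"] = df["school"].astype(float)
    return df, _ledger(rules)


def add_derived_columns(children: pd.DataFrame,
                        births: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derive firstborn flag, mother's age at birth and sibship size.

    ``number_of_siblings`` (children ever born to the mother) is counted from
    the full birth-history table when given, so that dead siblings count too.
    """
    df = children.copy()
    df["firstborn"] = df["preceding_interval_months"].isna()
    df["mother_age_at_birth"] = (
        (df["birth_month"] - df["mother_birth_month"]) / 12.0)
    df["mother_any_education"] = (df["mother_education_years"] > 0)
    source = births if births is not None else children
    sibs = source.groupby("mother_id")["child_id"].size().rename("number_of_siblings")
    df = df.merge(sibs, on="mother_id", how="left")
    return df


def build_covariates(records: pd.DataFrame, fe_level: str) -> pd.DataFrame:
    """Design columns per the covariate protocol.

    Firstborns have no preceding birth interval; they receive the mean
    interval of non-firstborns plus the ``firstborn`` indicator (dummy
    variable adjustment). Squared terms (child age, mother's age at birth)
    are formed before centering; every covariate is then mean-centered on
    this sample. Constant columns are dropped with a warning since they
    cannot be identified within groups.
    """
    if fe_level not in FE_LEVELS:
        raise ValueError(f"fe_level must be one of {FE_LEVELS}")
    df = records
    x = pd.DataFrame(index=df.index)
    x["age_months"] = df["age_months"].astype(float)
    x["age_months_sq"] = x["age_months"] ** 2
    x["birth_order"] = df["birth_order"].astype(float)
    interval = df["preceding_interval_months"].astype(float)
    nonfb_mean = interval.dropna().mean()
    if np.isnan(nonfb_mean):
        nonfb_mean = 0.0
    x["preceding_interval_months"] = interval.fillna(nonfb_mean)
    x["firstborn"] = df["preceding_interval_months"].isna().astype(float)
    x["female"] = df["female"].astype(float)
    x["twin"] = df["twin"].astype(float)
    if fe_level in ("neighborhood", "survey"):
        x["mother_education_years"] = df["mother_education_years"].astype(float)
        x["mother_age_at_birth"] = df["mother_age_at_birth"].astype(float)
        x["mother_age_at_birth_sq"] = x["mother_age_at_birth"] ** 2
        x["number_of_siblings"] = df["number_of_siblings"].astype(float)
    constant = x.columns[x.std(ddof=0) == 0.0]
    if len(constant):
        logger.warning("dropping constant covariate columns: %s", list(constant))
        x = x.drop(columns=list(constant))
    return x - x.mean()


def apply_group_rules(records: pd.DataFrame,
                      fe_level: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twin rule and degenerate-group exclusions; adds a ``group`` column.

    Sibling level: exposure cannot differ between twins, so one child per
    twin set is kept (the firstborn among those with valid data); mothers
    left with fewer than two valid children are then dropped. Neighborhood
    level: neighborhoods with a single valid child are dropped. Survey
    level: no exclusion.
    """
    if fe_level not in FE_LEVELS:
        raise ValueError(f"fe_level must be one of {FE_LEVELS}")
    df = records.copy()
    rules = []
    if fe_level == "sibling":
        n0 = len(df)
        is_twin = df["twin"].astype(bool)
        twins = df[is_twin]
        if len(twins):
            keep_ids = (twins.sort_values("birth_order")
                        .groupby(["mother_id", "birth_month"])  # one twin set
                        .head(1)["child_id"])
            df = pd.concat([df[~is_twin], df[df["child_id"].isin(keep_ids)]])
            df = df.sort_index()
        rules.append(("twin_rule", n0 - len(df)))
        n0 = len(df)
        sizes = df.groupby("mother_id")["child_id"].transform("size")
        df = df[sizes >= 2]
        rules.append(("no_sibling_with_valid_data", n0 - len(df)))
        df["group"] = df["mother_id"]
    elif fe_level == "neighborhood":
        n0 = len(df)
        sizes = df.groupby("neighborhood_id")["child_id"].transform("size")
        df = df[sizes >= 2]
        rules.append(("single_observation_neighborhood", n0 - len(df)))
        df["group"] = df["neighborhood_id"]
    else:
        rules.append(("none", 0))
        df["group"] = df["survey_id"]
    return df, _ledger(rules)
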
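"""Lesion-level TLS prevalence analysis.

Builds the prevalence table relating lesion covariates (body site, gender,
BCC subtype components, ulceration, age) to two binary outcomes: presence of
any TLS in the biopsy and presence of a primary-stage TLS.  Associations are
quantified with Wald odds ratios and Fisher exact tests against a declared
referent level; age is compared with a Student t-test after a normality
check.

A 30-lesion cohort table is packaged with the library (``load_table1``).  Its
covariates are transcribed from the published patient/lesion listing; the
per-lesion TLS status columns are a reconstruction chosen to be consistent
with every published cross-tabulation (the publication reports only the
margins), so all marginal statistics computed here are exact.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2, odds_ratio_wald, shapiro_normality, two_sample_t

__all__ = ["load_table1", "prevalence_table", "cohort_summary"]

#: factor -> (exposure level(s), referent level(s)) on the lesion table
_FACTORS = {
    "body_site": [("trunk", "head and neck"), ("extremity", "head and neck")],
    "gender": [("F", "M")],
    "infiltrative": [(1, 0)],
    "nodular": [(1, 0)],
    "superficial": [(1, 0)],
    "ulceration": [(1, 0)],
}


def load_table1() -> pd.DataFrame:
    """Packaged 30-lesion cohort table (one row per lesion).

    Columns: patient_id, lesion_id, age (NaN when unknown), gender
    (``F``/``M``/``unknown``), body_site, superficial/nodular/infiltrative
    (0/1 subtype components), ulceration (0/1), any_tls, primary_tls (0/1),
    tls_stage (none/aggregate/primary).
    """
    with resources.files("tmefib.data").joinpath("table1_lesions.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_summary(df: pd.DataFrame) -> dict:
    """Headline parse counts for a lesion table."""
    known = df.dropna(subset=["age"])
    pure_nodular = int(
        ((df["nodular"] == 1) & (df["superficial"] == 0) & (df["infiltrative"] == 0)).sum()
    )
    return {
        "n_lesions": int(len(df)),
        "n_patients": int(df["patient_id"].nunique()),
        "pure_nodular": pure_nodular,
        "ulcerated": int((df["ulceration"] == 1).sum()),
        "any_tls": int((df["any_tls"] == 1).sum()),
        "primary_tls": int((df["primary_tls"] == 1).sum()),
        "mean_age": float(known["age"].mean()),
    }


def _factor_rows(df, factor, pairs, outcome):
    rows = []
    for exposure, referent in pairs:
        exp = df[df[factor] == exposure]
        ref = df[df[factor] == referent]
        a = int((exp[outcome] == 1).sum())
        b = int((exp[outcome] == 0).sum())
        c = int((ref[outcome] == 1).sum())
        d = int((ref[outcome] == 0).sum())
        if min(a + b, c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            orr = (np.nan, np.nan, np.nan)
            p = np.nan
            flag = "degenerate margin"
        else:
            res = odds_ratio_wald(a, b, c, d)
            orr = (res.odds_ratio, res.ci_low, res.ci_high)
            p = fisher_exact_2x2(a, b, c, d)
            flag = "continuity-corrected" if res.continuity_corrected else ""
        rows.append(
            {
                "factor": factor,
                "level": str(exposure),
                "referent": str(referent),
                "outcome": outcome,
                "n_exposed": a + b,
                "n_outcome_exposed": a,
                "prop_exposed": a / (a + b) if a + b else np.nan,
                "n_referent": c + d,
                "n_outcome_referent": c,
                "prop_referent": c / (c + d) if c + d else np.nan,
                "odds_ratio": orr[0],
                "ci_low": orr[1],
                "ci_high": orr[2],
                "fisher_p": p,
                "note": flag,
            }
        )
    return rows


def prevalence_table(
    df: pd.DataFrame,
    outcomes: tuple[str, ...] = ("any_tls", "primary_tls"),
    welch: bool = False,
) -> pd.DataFrame:
    """Odds-ratio prevalence table over the standard lesion factors.

    Gender-unknown lesions are excluded from the gender rows and lesions of
    unknown age from the age row, but both remain in every other row.  The
    age row reports group means and the two-sample t-test p (Student pooled
    variance by default, Welch optional), run only when both outcome groups
    pass a Shapiro-Wilk normality check at alpha 0.05.
    """
    rows = []
    for outcome in outcomes:
        for factor, pairs in _FACTORS.items():
            sub = df
            if factor == "gender":
                sub = df[df["gender"].isin(["F", "M"])]
            rows.extend(_factor_rows(sub, factor, pairs, outcome))
        known = df.dropna(subset=["age"])
        pos = known.loc[known[outcome] == 1, "age"].to_numpy()
        neg = known.loc[known[outcome] == 0, "age"].to_numpy()
        enough = len(pos) >= 3 and len(neg) >= 3
        normal = enough and shapiro_normality(pos)[0] and shapiro_normality(neg)[0]
        t, p = two_sample_t(pos, neg, welch=welch) if normal else (np.nan, np.nan)
        rows.append(
            {
                "factor": "age",
                "level": "mean(outcome+)",
                "referent": "mean(outcome-)",
                "outcome": outcome,
                "n_exposed": len(pos),
                "n_outcome_exposed": np.nan,
                "prop_exposed": float(pos.mean()) if len(pos) else np.nan,
                "n_referent": len(neg),
                "n_outcome_referent": np.nan,
                "prop_referent": float(neg.mean()) if len(neg) else np.nan,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "fisher_p": p,
                "note": "t-test" if normal else "non-normal: t-test withheld",
            }
        )
    return pd.DataFrame(rows)


def lookup_or(table: pd.DataFrame, factor: str, outcome: str, level: str | None = None):
    """Convenience: (OR, ci_low, ci_high, fisher_p) for one table row."""
    sel = (table["factor"] == factor) & (table["outcome"] == outcome)
    if level is not None:
        sel &= table["level"] == str(level)
    row = table[sel].iloc[0]
    return (
        float(row["odds_ratio"]),
        float(row["ci_low"]),
        float(row["ci_high"]),
        float(row["fisher_p"]),
    )
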
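"""Cohort construction: eligibility, variable resolution, classification,
and the descriptive (Table-1-style) summary with its tests.

Rules implemented (registry conventions for prostate-cancer cohorts):

* Gleason score and tumor stage are resolved pathology-first: the pathology
  value is used whenever documented, otherwise the clinical value.
* Eligibility: age at diagnosis >= 40 (and present) and resolved Gleason
  score >= 6, or Gleason missing but resolved stage T3/T4.  Excluded cases
  are tallied under exactly one reason with fixed precedence
  (age first, then GS < 6, then missing-GS-without-T3/T4).
* Aggressiveness: "less" = GS 6 or 7 (3+4) and stage T1-T2 and no distant
  metastasis; "more" = GS >= 7 (4+3) or GS >= 8 or stage T3-T4 or
  metastasis; anything undecidable (e.g. GS 6 with unknown stage, or GS 7
  without pattern detail) is "unknown".
* Region: RUCC < 4 = metro (urban); crossed with the Appalachia flag.
* Descriptive summary: means (SD) + one-way ANOVA for continuous variables,
  counts (column %) + chi-square (no continuity correction) for categorical
  variables, with unknown/missing categories kept in the table but dropped
  from the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import CountyGraph

__all__ = [
    "resolve_gleason_and_stage",
    "resolve_cases",
    "apply_eligibility",
    "classify_aggressiveness",
    "classify_region",
    "describe_cohort",
]

EXCLUSION_REASONS = ("age_or_missing_age", "gs_below_6", "missing_gs_not_t34")
_STAGES = ("T1", "T2", "T3", "T4", "unknown")


def _pattern(v) -> int | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return int(v)


def resolve_gleason_and_stage(rec) -> tuple[tuple[int, int, int] | None, str]:
    """Resolve Gleason and stage pathology-first from one record.

    ``rec`` is a mapping (or pandas row) with fields
    ``gleason_{path,clin}_{primary,secondary}`` and ``stage_{path,clin}``.
    Returns ``((score, primary, secondary) | None, stage)`` where stage is
    one of T1-T4 or "unknown".
    """
    for src in ("path", "clin"):
        p = _pattern(rec.get(f"gleason_{src}_primary"))
        s = _pattern(rec.get(f"gleason_{src}_secondary"))
        if p is not None and s is not None:
            gleason = (p + s, p, s)
            break
    else:
        gleason = None
    stage = "unknown"
    for src in ("path", "clin"):
        v = rec.get(f"stage_{src}")
        if isinstance(v, str) and v in _STAGES[:4]:
            stage = v
            break
    return gleason, stage


def classify_aggressiveness(gleason, stage: str, metastasis: str) -> str:
    """Map resolved tumor variables to {less, more, unknown}; total on its
    domain (every combination yields exactly one label)."""
    score = gleason[0] if gleason is not None else None
    primary = gleason[1] if gleason is not None else None
    if (
        metastasis == "yes"
        or stage in ("T3", "T4")
        or (score is not None and score >= 8)
        or (score == 7 and primary is not None and primary >= 4)
    ):
        return "more"
    if (
        (score == 6 or (score == 7 and primary == 3))
        and stage in ("T1", "T2")
        and metastasis == "no"
    ):
        return "less"
    return "unknown"


def classify_region(appalachia: bool, rucc: int) -> str:
    """Cross rurality (RUCC < 4 = metro/urban) with the Appalachia flag."""
    urban = rucc < 4
    if appalachia:
        return "urban_appalachia" if urban else "rural_appalachia"
    return "urban_non_appalachia" if urban else "rural_non_appalachia"


def resolve_cases(cases: pd.DataFrame, graph: CountyGraph) -> pd.DataFrame:
    """Attach resolved Gleason/stage, aggressiveness, region and catchment.

    Unknown county ids raise ``KeyError`` naming the offending FIPS codes.
    """
    attrs = graph.attrs()
    missing = set(cases["county_fips"]) - set(attrs.index)
    if missing:
        raise KeyError(f"counties not in graph: {sorted(missing)[:10]}")
    out = cases.copy()
    gleason, stage = zip(*(resolve_gleason_and_stage(r) for _, r in cases.iterrows()))
    out["gleason_score"] = [g[0] if g else np.nan for g in gleason]
    out["gleason_primary"] = [g[1] if g else np.nan for g in gleason]
    out["gleason_secondary"] = [g[2] if g else np.nan for g in gleason]
    out["stage"] = stage
    out["aggressiveness"] = [
        classify_aggressiveness(g, s, m)
        for g, s, m in zip(gleason, stage, cases["metastasis"])
    ]
    out["region"] = [
        classify_region(attrs.loc[c, "appalachia"], attrs.loc[c, "rucc"])
        for c in cases["county_fips"]
    ]
    out["catchment"] = attrs.loc[cases["county_fips"], "catchment"].to_numpy()
    return out


def apply_eligibility(resolved: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Split resolved records into the eligible cohort and an exclusion tally.

    Eligible iff age present and >= 40 AND (Gleason score >= 6 OR Gleason
    missing with stage T3/T4).  Multiple violated rules resolve to one
    reason by precedence: age, then GS < 6, then missing-GS-without-T3/T4.
    """
    age = pd.to_numeric(resolved["age_at_dx"], errors="coerce")
    score = pd.to_numeric(resolved["gleason_score"], errors="coerce")
    stage34 = resolved["stage"].isin(["T3", "T4"])
    age_ok = age.notna() & (age >= 40)
    gs_ok = (score >= 6) | (score.isna() & stage34)
    eligible = age_ok & gs_ok

    reason = np.full(len(resolved), "none", dtype=object)
    reason[~gs_ok.to_numpy() & score.isna().to_numpy()] = "missing_gs_not_t34"
    reason[~gs_ok.to_numpy() & (score < 6).to_numpy()] = "gs_below_6"
    reason[~age_ok.to_numpy()] = "age_or_missing_age"  # highest precedence
    reason[eligible.to_numpy()] = "none"

    out = resolved.copy()
    out["eligible"] = eligible.to_numpy()
    out["exclusion_reason"] = reason
    tally = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    return out[out["eligible"]].copy(), tally


_CONTINUOUS = ("age_at_dx", "psa")
_UNKNOWN_LABELS = {"unknown", "other_unknown", "Unknown"}


def describe_cohort(
    eligible: pd.DataFrame,
    grouping: str = "catchment",
    continuous: tuple = _CONTINUOUS,
    categorical: tuple = (
        "race", "ethnicity", "insurance", "stage", "metastasis",
        "aggressiveness", "ln_positive", "treatment",
    ),
) -> dict:
    """Table-1-style descriptive summary with tests between groups.

    ``grouping`` is a column name ("catchment" or "region").  Returns a dict
    with a ``summary`` DataFrame (means(SD) / counts(col %)) and a ``tests``
    dict per variable: one-way ANOVA F/p for continuous, chi-square
    statistic/df/p (uncorrected) for categorical.  Unknown categories stay
    in the summary but are dropped from the tests.  Degenerate ANOVA groups
    (zero variance everywhere) are reported, not raised.
    """
    groups = eligible.groupby(grouping, observed=True)
    sizes = groups.size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 cases each")

    rows, tests = [], {}
    for var in continuous:
        vals = pd.to_numeric(eligible[var], errors="coerce")
        cells = {
            g: f"{sub.mean():.2f} ({sub.std():.2f})"
            for g, sub in vals.groupby(eligible[grouping], observed=True)
        }
        rows.append({"variable": var, "level": "mean (SD)", **cells})
        arrays = [
            sub.dropna().to_numpy()
            for _, sub in vals.groupby(eligible[grouping], observed=True)
        ]
        if all(np.ptp(a) == 0 for a in arrays if len(a)):
            tests[var] = {"test": "anova", "degenerate": True}
        else:
            f, p = stats.f_oneway(*arrays)
            tests[var] = {"test": "anova", "F": float(f), "p": float(p)}

    for var in categorical:
        ct = pd.crosstab(eligible[var], eligible[grouping])
        pct = 100 * ct / ct.sum(axis=0)
        for lev in ct.index:
            cells = {
                g: f"{ct.loc[lev, g]} ({pct.loc[lev, g]:.2f})" for g in ct.columns
            }
            rows.append({"variable": var, "level": str(lev), **cells})
        keep = [lev for lev in ct.index if str(lev) not in _UNKNOWN_LABELS]
        sub = ct.loc[keep]
        sub = sub.loc[sub.sum(axis=1) > 0, sub.sum(axis=0) > 0]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            tests[var] = {"test": "chi2", "degenerate": True}
        else:
            chi2, p, dof, _ = stats.chi2_contingency(sub, correction=False)
            tests[var] = {
                "test": "chi2", "statistic": float(chi2), "df": int(dof),
                "p": float(p),
            }
    return {"summary": pd.DataFrame(rows), "tests": tests, "group_sizes": sizes.to_dict()}
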
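"""Neuropsychological battery scoring.

Per test: a ROC analysis of patients vs controls yields a cut-off score
(Youden J = sensitivity + specificity - 1, ties broken toward higher
specificity), and a two-sided Mann-Whitney test screens which tests
discriminate patients from controls (P < 0.05). Each patient's impairment
score per cognitive domain (memory, language, executive) counts the
discriminative tests on whose impaired side the patient falls; the total
score over domains splits the cohort into severe (total > cohort mean)
and mild (total <= mean). A 2x2 Fisher exact test checks whether severe
impairment associates with the side of hippocampal sclerosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CognitiveBattery",
    "RocCutoff",
    "roc_cutoff",
    "mannwhitney",
    "screen_tests",
    "impairment_scores",
    "classify_severity",
    "laterality_association",
    "score_battery",
]

DOMAINS = ("memory", "language", "executive")


@dataclass
class CognitiveBattery:
    """Subjects (group/side), test metadata (domain/direction) and scores.

    ``scores`` is subject x test with NaN for missing; ``subjects`` has
    columns ``group`` ('patient' or 'control') and ``side`` ('left',
    'right', or '' for controls); ``tests`` is indexed by test name with
    columns ``domain`` and ``direction``.
    """

    subjects: pd.DataFrame
    tests: pd.DataFrame
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = set(self.tests["domain"]) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domain(s): {sorted(unknown)}")
        if not self.scores.index.equals(self.subjects.index):
            raise ValueError("scores and subjects must share the same subject index")

    def patient_ids(self, side: str | None = None) -> pd.Index:
        mask = self.subjects["group"] == "patient"
        if side is not None:
            mask &= self.subjects["side"] == side
        return self.subjects.index[mask]

    def control_ids(self) -> pd.Index:
        return self.subjects.index[self.subjects["group"] == "control"]


@dataclass
class RocCutoff:
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    youden: float

    @property
    def discriminative(self) -> bool:
        return self.youden > 0


def _impaired(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    if direction == "higher_better":
        return scores < cutoff
    return scores > cutoff


def roc_cutoff(
    patient_scores: np.ndarray, control_scores: np.ndarray, direction: str
) -> RocCutoff:
    """Best sensitivity/specificity cut-off from patient vs control scores.

    Candidate thresholds are the midpoints between adjacent distinct
    pooled values; the threshold maximizing Youden J is chosen, with ties
    broken toward higher specificity. AUC is the probability that a
    random patient scores on the impaired side of a random control
    (ties count 1/2).
    """
    pat = np.asarray(patient_scores, float)
    ctl = np.asarray(control_scores, float)
    pat, ctl = pat[~np.isnan(pat)], ctl[~np.isnan(ctl)]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("need at least 2 scored subjects per group")
    pooled = np.unique(np.concatenate([pat, ctl]))
    if len(pooled) < 2:
        raise ValueError("all scores identical: cut-off undefined")
    candidates = (pooled[:-1] + pooled[1:]) / 2
    best: RocCutoff | None = None
    for c in candidates:
        sens = float(_impaired(pat, c, direction).mean())
        spec = float((~_impaired(ctl, c, direction)).mean())
        j = sens + spec - 1
        if best is None or (j, spec) > (best.youden, best.specificity):
            best = RocCutoff(float(c), sens, spec, 0.0, j)
    # Mann-Whitney AUC with midrank ties, oriented toward "patients impaired"
    greater = (pat[:, None] > ctl[None, :]).mean() + 0.5 * (
        pat[:, None] == ctl[None, :]
    ).mean()
    auc = 1 - greater if direction == "higher_better" else greater
    assert best is not None
    best.auc = float(auc)
    if best.youden <= 0:
        log.info("non-discriminative test: best Youden J = %.3f", best.youden)
    return best


def mannwhitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of arrangements when both groups have at most
    8 observations and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    p = float(res.pvalue)
    if u1 == len(a) * len(b) / 2:  # perfectly central statistic
        p = 1.0
    return u1, min(p, 1.0)


def screen_tests(
    battery: CognitiveBattery, side: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Mann-Whitney patient-vs-control screen per test (per side subgroup)."""
    pats = battery.patient_ids(side)
    ctls = battery.control_ids()
    rows = []
    for test in battery.tests.index:
        u, p = mannwhitney(
            battery.scores.loc[pats, test], battery.scores.loc[ctls, test]
        )
        rows.append({"test": test, "U": u, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("test")


def fit_cutoffs(
    battery: CognitiveBattery, side: str | None = None
) -> pd.DataFrame:
    """ROC cut-off per test for the given patient subgroup vs controls."""
    pats = battery.patient_ids(side)
    ctls = battery.control_ids()
    rows = []
    for test, meta in battery.tests.iterrows():
        rc = roc_cutoff(
            battery.scores.loc[pats, test].to_numpy(),
            battery.scores.loc[ctls, test].to_numpy(),
            meta["direction"],
        )
        rows.append(
            {"test": test, "cutoff": rc.cutoff, "sensitivity": rc.sensitivity,
             "specificity": rc.specificity, "auc": rc.auc, "youden": rc.youden}
        )
    return pd.DataFrame(rows).set_index("test")


def impairment_scores(
    battery: CognitiveBattery,
    cutoffs: pd.DataFrame,
    significant_tests: list[str] | None = None,
    side: str | None = None,
) -> pd.DataFrame:
    """Per-patient impairment counts per domain plus the total score.

    Only ``significant_tests`` contribute (default: all tests). A missing
    test score is not counted and is logged; a patient missing every test
    of a domain gets a missing domain score.
    """
    if significant_tests is None:
        significant_tests = list(battery.tests.index)
    missing_cut = [t for t in significant_tests if t not in cutoffs.index]
    if missing_cut:
        raise ValueError(f"no cut-off for test(s): {missing_cut}")
    pats = battery.patient_ids(side)
    out = pd.DataFrame(index=pats, columns=[*DOMAINS, "total"], dtype=float)
    for pid in pats:
        total = 0.0
        any_domain = False
        for domain in DOMAINS:
            tests = [
                t for t in significant_tests if battery.tests.loc[t, "domain"] == domain
            ]
            if not tests:
                out.loc[pid, domain] = 0.0
                continue
            count, seen = 0, 0
            for t in tests:
                score = battery.scores.loc[pid, t]
                if pd.isna(score):
                    log.info("subject %s missing test %s: not counted", pid, t)
                    continue
                seen += 1
                if _impaired(
                    np.asarray([score]), cutoffs.loc[t, "cutoff"],
                    battery.tests.loc[t, "direction"],
                )[0]:
                    count += 1
            if seen == 0:
                out.loc[pid, domain] = np.nan
            else:
                out.loc[pid, domain] = count
                total += count
                any_domain = True
        out.loc[pid, "total"] = total if any_domain else np.nan
    return out


def classify_severity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Split patients into severe (total > cohort mean) vs mild (<= mean)."""
    totals = profiles["total"].dropna()
    if len(totals) < 2:
        raise ValueError("need at least 2 patients with total scores")
    mean = totals.mean()
    out = profiles.copy()
    out["severity"] = np.where(out["total"] > mean, "severe", "mild")
    out.loc[out["total"].isna(), "severity"] = ""
    return out


def laterality_association(
    profiles: pd.DataFrame, sides: pd.Series
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test of severity vs HS side.

    Returns the 2x2 table [[left severe, left mild], [right severe,
    right mild]] and the p-value.
    """
    sides = sides.reindex(profiles.index)
    table = np.zeros((2, 2), dtype=int)
    for i, side in enumerate(("left", "right")):
        sub = profiles.loc[sides == side, "severity"]
        table[i, 0] = int((sub == "severe").sum())
        table[i, 1] = int((sub == "mild").sum())
    if (table.sum(axis=1) == 0).any():
        raise ValueError("one side has no classified patients")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def score_battery(
    battery: CognitiveBattery,
    alpha: float = 0.05,
    only_significant: bool = True,
    by_side: bool = True,
) -> pd.DataFrame:
    """Full scoring flow: screen, cut-offs, impairment scores, severity.

    With ``by_side`` the Mann-Whitney screen and ROC cut-offs are fitted
    per HS-side subgroup (mirroring separate left/right analyses);
    severity is classified on the pooled patient cohort.
    """
    sides = (
        sorted(s for s in battery.subjects["side"].unique() if s)
        if by_side
        else [None]
    )
    parts = []
    for side in sides:
        screen = screen_tests(battery, side=side, alpha=alpha)
        cuts = fit_cutoffs(battery, side=side)
        tests = (
            list(screen.index[screen["significant"]])
            if only_significant
            else list(battery.tests.index)
        )
        parts.append(impairment_scores(battery, cuts, tests, side=side))
    profiles = pd.concat(parts)
    return classify_severity(profiles)
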
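"""Reader-study agreement statistics.

Paired categorical ratings (one per rater x patient x question x arm,
arms being the synthetic and the contrast-based perfusion series) are
pooled into a two-arm comparison per question.  Reported per question:
percent agreement with a Wilson score 95% CI, and unweighted Cohen's kappa
with an asymptotic (Fleiss-Cohen-Everitt) 95% CI.  A Monte-Carlo power
routine estimates the probability of detecting a given kappa alternative
with the asymptotic z-test under user-specified marginals.

When one arm's responses are (nearly) constant, expected chance agreement
approaches the observed agreement and kappa collapses toward zero even at
high raw agreement - both statistics are therefore always reported side by
side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

QUESTION_IDS = ("1", "2A", "2B", "2C", "2D", "3", "4")
QUESTION_CATEGORIES = {"3": (1, 2, 3, 4), "4": (1, 2, 3, 4, 5)}
ARMS = ("synthetic", "real")

RATING_COLUMNS = ["rater", "patient", "question", "arm", "response"]


class RatingTableError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementResult:
    """Pooled two-arm agreement for one question."""

    question: str
    n_pairs: int
    agreement: float
    agreement_ci: tuple
    kappa: float
    kappa_ci: tuple
    n_dropped: int = 0


def validate_rating_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema and uniqueness checks; returns a normalized copy."""
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise RatingTableError(f"missing columns: {missing}")
    df = table[RATING_COLUMNS].copy()
    df["question"] = df["question"].astype(str)
    df["arm"] = df["arm"].astype(str)
    unknown = sorted(set(df["question"]) - set(QUESTION_IDS))
    if unknown:
        raise RatingTableError(f"unknown question ids: {unknown}")
    bad_arms = sorted(set(df["arm"]) - set(ARMS))
    if bad_arms:
        raise RatingTableError(f"unknown arms: {bad_arms}")
    dup = df.duplicated(subset=["rater", "patient", "question", "arm"])
    if dup.any():
        raise RatingTableError(
            f"{int(dup.sum())} duplicate (rater, patient, question, arm) rows")
    for q, cats in QUESTION_CATEGORIES.items():
        resp = df.loc[df["question"] == q, "response"]
        bad = sorted(set(resp.astype(int)) - set(cats)) if len(resp) else []
        if bad:
            raise RatingTableError(
                f"question {q} responses outside categories {cats}: {bad}")
    return df


def percent_agreement_ci(a, b, conf: float = 0.95):
    """Proportion of exact matches with a Wilson score interval.

    ``a`` and ``b`` are the paired responses (one entry per complete
    rater-patient pair).  Returns ``(p_hat, lo, hi)`` as proportions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("paired responses differ in length")
    n = a.size
    if n < 1:
        raise ValueError("need at least one complete pair")
    k = int((a == b).sum())
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # the Wilson bounds are analytically exact at the extremes
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return k / n, lo, hi


def _contingency(a, b):
    cats = sorted(set(np.asarray(a).tolist()) | set(np.asarray(b).tolist()))
    index = {c: i for i, c in enumerate(cats)}
    tab = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        tab[index[x], index[y]] += 1
    return tab


def kappa_and_se(a, b):
    """Unweighted Cohen's kappa and its asymptotic standard error.

    The SE follows the Fleiss-Cohen-Everitt large-sample formula.  A
    degenerate table where chance agreement equals one (both margins on a
    single category) yields ``(0.0, 0.0)``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("paired responses differ in length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two complete pairs")
    p = _contingency(a, b) / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if 1.0 - pe < 1e-12:
        return 0.0, 0.0
    kappa = (po - pe) / (1.0 - pe)

    diag = np.diag(p)
    term_a = float(np.sum(diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    sums = col[None, :] + row[:, None]      # p_.j + p_i. for cell (i, j)
    term_b = float((1.0 - kappa) ** 2 * np.sum(off * sums ** 2))
    term_c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (term_a + term_b - term_c) / (n * (1.0 - pe) ** 2)
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def cohens_kappa_ci(a, b, conf: float = 0.95):
    """Kappa with an asymptotic CI truncated to [-1, 1]; see
    :func:`kappa_and_se` for the variance formula and degenerate case."""
    kappa, se = kappa_and_se(a, b)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return kappa, float(max(kappa - z * se, -1.0)), \
        float(min(kappa + z * se, 1.0))


def _paired_responses(df: pd.DataFrame, question: str):
    sub = df[df["question"] == question]
    wide = sub.pivot_table(index=["rater", "patient"], columns="arm",
                           values="response", aggfunc="first")
    n_units = len(wide)
    wide = wide.dropna(subset=[a for a in ARMS if a in wide.columns])
    if not all(a in wide.columns for a in ARMS):
        return np.array([]), np.array([]), n_units
    return (wide["synthetic"].to_numpy(), wide["real"].to_numpy(),
            n_units - len(wide))


def agreement_report(table: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """One row per question: n, percent agreement (CI), kappa (CI).

    Responses are pooled over raters and patients; pairs missing either
    arm are dropped and counted in ``n_dropped``.
    """
    df = validate_rating_table(table)
    rows = []
    for q in QUESTION_IDS:
        if not (df["question"] == q).any():
            continue
        a, b, dropped = _paired_responses(df, q)
        if a.size == 0:
            continue
        p, plo, phi = percent_agreement_ci(a, b, conf)
        k, klo, khi = cohens_kappa_ci(a, b, conf)
        rows.append({"question": q, "n_pairs": a.size, "n_dropped": dropped,
                     "agreement_pct": 100 * p,
                     "agreement_lo_pct": 100 * plo,
                     "agreement_hi_pct": 100 * phi,
                     "kappa": k, "kappa_lo": klo, "kappa_hi": khi})
    return pd.DataFrame(rows)


def kappa_power_simulation(kappa_alt: float, n: int, marginals,
                           alpha: float = 0.05, reps: int = 1000,
                           seed: int = 0):
    """Monte-Carlo power of the asymptotic two-sided kappa z-test.

    Paired ratings are drawn from the joint distribution
    ``p_ij = kappa * p_i * 1[i == j] + (1 - kappa) * p_i * p_j`` which has
    the given common marginals and true kappa equal to ``kappa_alt``.
    Returns ``(power, mc_se)``.
    """
    marginals = np.asarray(marginals, dtype=float)
    if marginals.ndim != 1 or len(marginals) < 2 or np.any(marginals <= 0):
        raise ValueError("marginals must be >= 2 strictly positive masses")
    if abs(marginals.sum() - 1.0) > 1e-8:
        raise ValueError("marginals must sum to 1")
    if not 0.0 <= kappa_alt < 1.0:
        raise ValueError("kappa_alt must be in [0, 1)")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    k_cat = len(marginals)
    joint = (1.0 - kappa_alt) * np.outer(marginals, marginals) \
        + kappa_alt * np.diag(marginals)
    cells = joint.ravel()
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    rejections = 0
    for _ in range(reps):
        counts = rng.multinomial(n, cells)
        idx = np.repeat(np.arange(k_cat * k_cat), counts)
        a, b = idx // k_cat, idx % k_cat
        k_hat, se = kappa_and_se(a, b)
        if se > 0 and abs(k_hat) / se > z_crit:
            rejections += 1
    power = rejections / reps
    mc_se = float(np.sqrt(power * (1.0 - power) / reps))
    return power, mc_se
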
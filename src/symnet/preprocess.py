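"""Pre-estimation preparation: composite scoring, dichotomization,
covariate adjustment and redundant-node screening.

Risk factors measured on a continuous or ordinal scale enter the binary
network dichotomized at the sample 75th centile (capturing *increased*
exposure); polygenic scores are first residualized on genetic principal
components; a cumulative-trauma composite sums 15 ordinal trauma items; and
a redundancy screen ("goldbricker") flags node pairs so highly correlated
and so similar in their correlation profiles that they likely measure the
same construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "recode_ptsd_items",
    "reverse_code",
    "score_cumulative_trauma",
    "dichotomize_q75",
    "residualize",
    "goldbricker",
    "RedundancyReport",
    "dependent_correlation_test",
]


# ---------------------------------------------------------------------------
# trauma composite
# ---------------------------------------------------------------------------

def recode_ptsd_items(raw: pd.DataFrame) -> pd.DataFrame:
    """Recode PTSD-relevant trauma items from a 3-point to a 2-point scale.

    Raw coding: 0 = never; 1 = yes, but not in the last 12 months;
    2 = yes, within the last 12 months.  Because the analysis concerns
    *lifetime* exposure, and so the trauma measures share a 0-4 range,
    both "yes" answers are recoded to 4: {0 -> 0, 1 -> 4, 2 -> 4}.
    """
    arr = raw.to_numpy()
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("raw PTSD items must be coded 0/1/2")
    return raw.where(raw == 0, 4).astype(int)


def reverse_code(items: pd.DataFrame, reverse: list[str],
                 max_score: int = 4) -> pd.DataFrame:
    """Reverse-code the named ordinal columns (x -> max_score - x) so that
    higher scores always represent more severe experience."""
    unknown = [c for c in reverse if c not in items.columns]
    if unknown:
        raise ValueError(f"reverse-code map names unknown column(s): {unknown}")
    out = items.copy()
    for c in reverse:
        out[c] = max_score - out[c]
    return out


@dataclass
class TraumaItems:
    """The 15 ordinal trauma items entering the cumulative-trauma composite.

    ``child`` and ``adult`` each hold 5 items on a 0-4 scale ("never true"
    ... "very often true", already reverse-coded where required); ``ptsd``
    holds 5 items recoded to {0, 4} (see :func:`recode_ptsd_items`).
    """

    child: pd.DataFrame
    adult: pd.DataFrame
    ptsd: pd.DataFrame

    def __post_init__(self):
        for name, frame, k in (("child", self.child, 5),
                               ("adult", self.adult, 5),
                               ("ptsd", self.ptsd, 5)):
            if frame.shape[1] != k:
                raise ValueError(f"{name} trauma block must have {k} items, "
                                 f"got {frame.shape[1]}")
            arr = frame.to_numpy()
            if not np.isin(arr, (0, 1, 2, 3, 4)).all():
                raise ValueError(f"{name} trauma items out of 0-4 range")
        if not np.isin(self.ptsd.to_numpy(), (0, 4)).all():
            raise ValueError("ptsd items must be recoded to {0, 4}")
        n = len(self.child)
        if len(self.adult) != n or len(self.ptsd) != n:
            raise ValueError("trauma blocks have inconsistent lengths")


def score_cumulative_trauma(items: TraumaItems) -> pd.Series:
    """Cumulative trauma: the sum over all 15 items (range 0-60)."""
    total = (items.child.sum(axis=1).to_numpy()
             + items.adult.sum(axis=1).to_numpy()
             + items.ptsd.sum(axis=1).to_numpy())
    return pd.Series(total.astype(int), index=items.child.index,
                     name="cumulative_trauma")


# ---------------------------------------------------------------------------
# dichotomization and adjustment
# ---------------------------------------------------------------------------

def dichotomize_q75(x: pd.Series | np.ndarray) -> pd.Series:
    """Indicator of exceeding the sample 75th centile.

    The centile uses the linear-interpolation quantile definition and the
    comparison is strict, so values tied with the cut point are coded 0.
    For a tie-free sample the proportion of ones is 25% up to rounding; tie
    mass exactly at the quantile reduces it.
    """
    s = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x
    vals = s.to_numpy(dtype=float)
    if np.unique(vals).size < 4:
        raise ValueError("dichotomize_q75 requires at least 4 distinct values")
    q = np.quantile(vals, 0.75)  # linear interpolation (type 7)
    out = (vals > q).astype(np.int8)
    return pd.Series(out, index=s.index, name=s.name)


def residualize(x: pd.Series | np.ndarray, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of x on the covariates plus an intercept.

    Used to adjust polygenic scores for genetic principal components; the
    residuals are exactly orthogonal to every covariate and to the
    intercept (hence mean zero).
    """
    xv = np.asarray(x, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(xv)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates (plus intercept) are rank deficient")
    beta, *_ = np.linalg.lstsq(X, xv, rcond=None)
    resid = xv - X @ beta
    index = x.index if isinstance(x, pd.Series) else None
    name = x.name if isinstance(x, pd.Series) else None
    return pd.Series(resid, index=index, name=name)


# ---------------------------------------------------------------------------
# goldbricker redundancy screen
# ---------------------------------------------------------------------------

def dependent_correlation_test(r_jk: float, r_jh: float, r_kh: float,
                               n: int) -> float:
    """Two-sided p-value for H0: rho_jk = rho_jh (overlapping variable j).

    Back-transformed average z method (Hittner, May & Silver): the two
    dependent correlations are Fisher-transformed, their covariance is
    approximated using the back-transformed mean correlation, and the
    difference is referred to a standard normal.
    """
    if n < 4:
        raise ValueError("dependent correlation test requires n >= 4")
    r_jk = float(np.clip(r_jk, -0.9999999, 0.9999999))
    r_jh = float(np.clip(r_jh, -0.9999999, 0.9999999))
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    r_bar = np.tanh(0.5 * (z_jk + z_jh))
    rb2 = r_bar * r_bar
    c = (r_kh * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_kh ** 2)) \
        / (1 - rb2) ** 2
    c = float(np.clip(c, -0.9999999, 0.9999999))
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * c))
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class RedundancyReport:
    """Outcome of the goldbricker screen.

    ``flagged_pairs`` lists ``(node_a, node_b, zero_order_r,
    prop_significantly_different)`` for every pair judged redundant; the
    full per-pair proportions are retained in ``proportions`` for auditing.
    """

    flagged_pairs: list[tuple[str, str, float, float]]
    proportions: dict[tuple[str, str], float]
    settings: dict

    @property
    def is_empty(self) -> bool:
        return len(self.flagged_pairs) == 0

    def to_dict(self) -> dict:
        return {
            "flagged_pairs": [
                {"node_a": a, "node_b": b, "zero_order_r": r,
                 "prop_significantly_different": prop}
                for a, b, r, prop in self.flagged_pairs
            ],
            "settings": self.settings,
        }


def goldbricker(items, cor_min: float = 0.5, threshold: float = 0.25,
                alpha: float = 0.01) -> RedundancyReport:
    """Flag node pairs that plausibly measure the same construct.

    A pair (A, B) is a redundancy candidate when its zero-order Pearson
    correlation satisfies ``|r_AB| >= cor_min`` with p < alpha.  For every
    third node C, the dependent-correlations test compares rho_AC with
    rho_BC; the pair is flagged as redundant when fewer than ``threshold``
    of these comparisons reject at ``alpha`` (i.e. the two nodes relate to
    the rest of the network near-identically).

    Parameters
    ----------
    items : ItemMatrix or DataFrame
        Data to screen (binary columns enter as 0/1, so Pearson r is the
        phi coefficient).
    """
    values = items.values if hasattr(items, "values") and hasattr(items, "meta") \
        else pd.DataFrame(items)
    names = list(values.columns)
    p = len(names)
    if p < 3:
        raise ValueError("goldbricker requires at least 3 nodes")
    n = len(values)
    if n < 4:
        raise ValueError("goldbricker requires n >= 4")
    X = values.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [names[i] for i in np.nonzero(X.std(axis=0) == 0)[0]]
        raise ValueError(f"constant column(s) cannot be screened: {const}")
    R = np.corrcoef(X, rowvar=False)

    flagged = []
    proportions: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(p), 2):
        r_ab = R[i, j]
        # significance of the zero-order correlation itself
        t = r_ab * np.sqrt((n - 2) / max(1e-300, 1 - r_ab ** 2))
        p_ab = 2 * stats.t.sf(abs(t), df=n - 2)
        if abs(r_ab) < cor_min or p_ab >= alpha:
            continue
        n_sig = 0
        n_tests = 0
        for k in range(p):
            if k in (i, j):
                continue
            pval = dependent_correlation_test(R[i, k], R[j, k], r_ab, n)
            n_tests += 1
            if pval < alpha:
                n_sig += 1
        prop = n_sig / n_tests if n_tests else 0.0
        proportions[(names[i], names[j])] = prop
        if prop < threshold:
            flagged.append((names[i], names[j], float(r_ab), float(prop)))
    return RedundancyReport(
        flagged_pairs=flagged,
        proportions=proportions,
        settings={"cor_min": cor_min, "threshold": threshold, "alpha": alpha,
                  "n": n, "method": "hittner-may-silver"},
    )
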
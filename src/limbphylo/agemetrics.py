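"""Transcriptome age indices and the VTAI flatness test.

TAI at one stage is the expression-weighted mean phylostratum,

    TAI_s = sum_i ps_i * e_i / sum_i e_i,

so smaller values mean an evolutionarily younger transcriptome.  Flatness of
the stage profile is tested with VTAI, the variance of TAI across stages:
the null is built by permuting the phylostratum labels over genes (one
shared permutation per surrogate, applied to every stage so cross-stage
expression correlation is preserved), the surrogate VTAI distribution is
fitted with a gamma, and the p-value is the fitted upper tail at the
observed VTAI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAGE_ORDER = ("ridge", "bud", "paddle")

#: smaller ps / TAI = younger; kept as an explicit constant to avoid sign
#: confusion in downstream interpretation.
YOUNGER_IS_SMALLER = True

FLAT_TOL = 1e-6


def compute_tai(expression: pd.Series, ps: pd.Series) -> float:
    """Expression-weighted mean phylostratum of one condition profile."""
    missing = expression.index.difference(ps.index)
    if len(missing):
        raise ValueError(f"genes without phylostratum: {list(missing[:5])}")
    e = expression.values.astype(float)
    if (e < 0).any():
        raise ValueError("expression must be non-negative")
    total = e.sum()
    if total <= 0:
        raise ValueError("all-zero expression: TAI undefined")
    p = ps.loc[expression.index].values.astype(float)
    return float((p * e).sum() / total)


def classify_shape(values: dict[str, float], tol: float = FLAT_TOL) -> str:
    """Trend shape over ridge -> bud -> paddle TAI values."""
    r, b, p = (values[s] for s in STAGE_ORDER)
    if max(r, b, p) - min(r, b, p) <= tol:
        return "flat"
    if b > r + tol and b > p + tol:
        return "hourglass"
    if b < r - tol and b < p - tol:
        return "reverse_hourglass"
    return "monotone"


@dataclass
class TAIProfile:
    """Per-stage TAI for one (species, limb) dataset."""

    values: dict[str, float]
    n: int
    species: str = ""
    limb: str = ""

    @property
    def shape(self) -> str:
        return classify_shape(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series({s: self.values[s] for s in STAGE_ORDER}, name="TAI")


def tai_profile(
    stage_expression: dict[str, pd.Series],
    ps: pd.Series,
    species: str = "",
    limb: str = "",
) -> TAIProfile:
    """One TAI per stage over an identical gene universe."""
    if set(stage_expression) != set(STAGE_ORDER):
        raise ValueError(f"stages must be exactly {set(STAGE_ORDER)}")
    universes = {s: frozenset(e.index) for s, e in stage_expression.items()}
    ref = universes[STAGE_ORDER[0]]
    for s, uni in universes.items():
        if uni != ref:
            diff = sorted(uni ^ ref)[:5]
            raise ValueError(f"gene sets differ between stages (e.g. {diff})")
    values = {s: compute_tai(stage_expression[s], ps) for s in STAGE_ORDER}
    return TAIProfile(
        values=values, n=len(ref), species=species, limb=limb
    )


def _vtai(tai_values: np.ndarray, ddof: int = 0) -> float:
    return float(np.var(tai_values, ddof=ddof))


@dataclass
class VTAITestResult:
    vtai_observed: float
    null_surrogates: np.ndarray
    gamma_shape: float
    gamma_rate: float
    p_value: float
    p_empirical: float
    seed: int | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "vtai_observed": self.vtai_observed,
            "gamma_shape": self.gamma_shape,
            "gamma_rate": self.gamma_rate,
            "p_value": self.p_value,
            "p_empirical": self.p_empirical,
            "n_perm": int(len(self.null_surrogates)),
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def vtai_test(
    stage_expression: dict[str, pd.Series],
    ps: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
    ddof: int = 0,
) -> VTAITestResult:
    """Permutation test of TAI-profile flatness with a gamma-modeled null.

    Each surrogate permutes the ps assignments over genes (shared across
    stages) and recomputes VTAI; the null is a maximum-likelihood gamma fit
    (moment matching on failure) and p = 1 - CDF(VTAI_obs).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = stage_expression[STAGE_ORDER[0]].index
    profile = tai_profile(stage_expression, ps)
    observed = _vtai(profile.as_series().values, ddof=ddof)

    e = np.column_stack(
        [stage_expression[s].loc[genes].values.astype(float) for s in STAGE_ORDER]
    )
    totals = e.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero expression at some stage")
    p_vec = ps.loc[genes].values.astype(float)

    rng = np.random.default_rng(seed)
    surrogates = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(p_vec)
        tais = (perm @ e) / totals
        surrogates[i] = _vtai(tais, ddof=ddof)

    p_emp = float((np.sum(surrogates >= observed) + 1) / (n_perm + 1))
    if np.allclose(surrogates, surrogates[0]):
        warnings.warn(
            "degenerate null (all surrogates equal); reporting empirical p",
            stacklevel=2,
        )
        return VTAITestResult(
            vtai_observed=observed,
            null_surrogates=surrogates,
            gamma_shape=float("nan"),
            gamma_rate=float("nan"),
            p_value=p_emp,
            p_empirical=p_emp,
            seed=seed,
            degenerate=True,
        )
    try:
        shape, _, scale = stats.gamma.fit(surrogates, floc=0.0)
    except Exception:  # MLE failure: moment matching
        mean, var = surrogates.mean(), surrogates.var()
        shape = mean**2 / var
        scale = var / mean
    p_gamma = float(stats.gamma.sf(observed, shape, loc=0.0, scale=scale))
    return VTAITestResult(
        vtai_observed=observed,
        null_surrogates=surrogates,
        gamma_shape=float(shape),
        gamma_rate=float(1.0 / scale),
        p_value=p_gamma,
        p_empirical=p_emp,
        seed=seed,
    )
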
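"""Broad-sense heritability from replicated accession panels.

Each trait is modelled with a one-way random-intercept model

    P_ij = mu + G_i + e_ij,   G_i ~ N(0, var_G),  e_ij ~ N(0, var_e)

where ``i`` indexes accessions (near-isogenic lines, so the line effect is
the genotype effect) and ``j`` replicates within a line.  Broad-sense
heritability — also called repeatability — is the variance ratio

    H² = var_G / (var_G + var_e).

Variance components are estimated by restricted maximum likelihood (REML),
which is exact here: for a single random intercept the REML criterion can
be profiled down to a one-dimensional optimization over the variance ratio
``lambda = var_G / var_e``, with the boundary ``lambda = 0`` checked
explicitly.  On balanced designs with ``MSB >= MSW`` the solution coincides
with the classical ANOVA method-of-moments estimator
``var_G = (MSB − MSW)/k``, ``var_e = MSW``.  Negative genotype variance is
truncated at zero, so ``H² ∈ [0, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """REML variance components and heritability for one trait."""

    var_g: float
    var_e: float
    h2: float
    n_accessions: int
    n_total: int
    trait: str | None = None
    #: Pearson correlation between model residuals and fitted values;
    #: advisory diagnostic for the equal-variance/normality check.
    resid_fitted_r: float = float("nan")

    def summary(self) -> str:
        lines = [
            f"Trait:            {self.trait or '-'}",
            f"Accessions:       {self.n_accessions}",
            f"Observations:     {self.n_total}",
            f"Var(G):           {self.var_g:.6g}",
            f"Var(e):           {self.var_e:.6g}",
            f"H2:               {self.h2:.4f} ({100 * self.h2:.1f}%)",
            f"resid~fitted r:   {self.resid_fitted_r:.3f}",
        ]
        return "\n".join(lines)


def heritability(vc: VarianceComponents) -> float:
    """H² = var_G / (var_G + var_e); NaN when the total variance is zero."""
    total = vc.var_g + vc.var_e
    if total <= 0:
        logger.warning("zero total variance: H2 undefined")
        return float("nan")
    return vc.var_g / total


def _prepare(trait: Iterable) -> tuple[np.ndarray, np.ndarray]:
    """Accept a sequence of (accession, value) pairs or a 2-column frame."""
    if isinstance(trait, pd.DataFrame):
        acc = trait.iloc[:, 0].to_numpy()
        val = trait.iloc[:, 1].to_numpy(dtype=np.float64)
    else:
        pairs = list(trait)
        acc = np.array([p[0] for p in pairs])
        val = np.array([p[1] for p in pairs], dtype=np.float64)
    keep = np.isfinite(val)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d missing value(s)", dropped)
    return acc[keep], val[keep]


def fit_random_effects(
    trait: Iterable,
    values: Sequence[float] | None = None,
    trait_name: str | None = None,
) -> VarianceComponents:
    """Fit the one-way random-intercept model by REML.

    ``trait`` is either an iterable of ``(accession_id, value)`` pairs, a
    two-column DataFrame, or — when ``values`` is given — the accession ids
    alone.  Missing values are dropped with a logged count.  Requires at
    least two accessions and at least one accession with two or more
    replicates (otherwise ``var_e`` is unidentifiable).
    """
    if values is not None:
        acc = np.asarray(list(trait))
        val = np.asarray(values, dtype=np.float64)
        keep = np.isfinite(val)
        if (~keep).any():
            logger.info("dropping %d missing value(s)", int((~keep).sum()))
        acc, val = acc[keep], val[keep]
    else:
        acc, val = _prepare(trait)

    uniq, idx = np.unique(acc, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError(f"need >= 2 accessions, got {a}")
    n_i = np.bincount(idx)
    n_total = int(val.size)
    if n_i.max() < 2:
        raise ValueError(
            "all accessions are singletons: residual variance unidentifiable"
        )

    sums = np.bincount(idx, weights=val)
    ybar = sums / n_i
    ssw = float(((val - ybar[idx]) ** 2).sum())

    def neg2reml(lam: float) -> float:
        w = n_i / (1.0 + lam * n_i)
        total_w = w.sum()
        mu = (w * ybar).sum() / total_w
        s = ssw + (w * (ybar - mu) ** 2).sum()
        if s <= 0:
            # degenerate: all values identical within the GLS fit
            return -np.inf
        return (n_total - 1) * np.log(s) + np.log1p(lam * n_i).sum() + np.log(total_w)

    if ssw == 0.0 and np.ptp(ybar) > 0:
        # replicates identical within accessions but accessions differ:
        # var_e -> 0, lambda -> infinity; H2 = 1
        mu = ybar.mean()
        var_g = float(((ybar - mu) ** 2).sum() / (a - 1))
        vc = VarianceComponents(var_g, 0.0, 1.0, a, n_total, trait_name)
        vc.resid_fitted_r = float("nan")
        return vc
    if np.ptp(val) == 0:
        logger.warning("constant trait: variance components are zero")
        return VarianceComponents(0.0, 0.0, float("nan"), a, n_total, trait_name)

    f0 = neg2reml(0.0)
    res = minimize_scalar(
        lambda t: neg2reml(np.exp(t)),
        bounds=(-30.0, 30.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    lam = float(np.exp(res.x)) if res.fun < f0 else 0.0

    w = n_i / (1.0 + lam * n_i)
    mu = (w * ybar).sum() / w.sum()
    s = ssw + float((w * (ybar - mu) ** 2).sum())
    var_e = s / (n_total - 1)
    var_g = max(0.0, lam * var_e)
    h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else float("nan")

    # advisory diagnostic: BLUP-fitted values vs residuals
    shrink = lam * n_i / (1.0 + lam * n_i)
    fitted = mu + shrink[idx] * (ybar[idx] - mu)
    resid = val - fitted
    if np.std(fitted) > 0 and np.std(resid) > 0:
        diag = float(np.corrcoef(resid, fitted)[0, 1])
    else:
        diag = float("nan")
    return VarianceComponents(var_g, var_e, h2, a, n_total, trait_name, diag)


def anova_components(
    trait: Iterable, values: Sequence[float] | None = None
) -> tuple[float, float]:
    """Closed-form balanced one-way ANOVA estimator (method of moments).

    ``var_G = max(0, (MSB − MSW)/k)``, ``var_e = MSW``; requires a balanced
    design (equal replicates per accession).  Intended as an independent
    cross-check of the REML fit on balanced data.
    """
    if values is not None:
        acc = np.asarray(list(trait))
        val = np.asarray(values, dtype=np.float64)
    else:
        acc, val = _prepare(trait)
    uniq, idx = np.unique(acc, return_inverse=True)
    n_i = np.bincount(idx)
    if np.ptp(n_i) != 0:
        raise ValueError("ANOVA estimator requires a balanced design")
    a, k = uniq.size, int(n_i[0])
    if k < 2:
        raise ValueError("need >= 2 replicates per accession")
    ybar = np.bincount(idx, weights=val) / n_i
    mu = val.mean()
    msb = k * float(((ybar - mu) ** 2).sum()) / (a - 1)
    msw = float(((val - ybar[idx]) ** 2).sum()) / (a * (k - 1))
    return max(0.0, (msb - msw) / k), msw


def heritability_report(
    table: pd.DataFrame,
    trait_columns: Sequence[str] | None = None,
    accession_col: str = "accession_id",
) -> pd.DataFrame:
    """Per-trait variance components and H² for a plants × traits table.

    ``trait_columns`` defaults to every numeric column except bookkeeping
    ones.  Traits with no usable variation (all missing, or constant) are
    skipped with a warning.  Returns a table with one row per trait:
    var_G, var_e, H2, accession and observation counts, and the
    residual-vs-fitted correlation diagnostic.
    """
    if accession_col not in table.columns:
        raise ValueError(f"table has no {accession_col!r} column")
    if trait_columns is None:
        skip = {accession_col, "sample_id", "replicate"}
        trait_columns = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for trait in trait_columns:
        vals = table[trait].to_numpy(dtype=np.float64)
        acc = table[accession_col].to_numpy()
        finite = np.isfinite(vals)
        if finite.sum() < 4 or np.ptp(vals[finite]) == 0:
            logger.warning("trait %s skipped (missing or constant)", trait)
            continue
        try:
            vc = fit_random_effects(acc[finite], vals[finite], trait_name=trait)
        except ValueError as exc:
            logger.warning("trait %s skipped: %s", trait, exc)
            continue
        rows.append(
            {
                "trait": trait,
                "var_G": vc.var_g,
                "var_e": vc.var_e,
                "H2": vc.h2,
                "n_accessions": vc.n_accessions,
                "n_total": vc.n_total,
                "resid_fitted_r": vc.resid_fitted_r,
            }
        )
    return pd.DataFrame(rows)
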
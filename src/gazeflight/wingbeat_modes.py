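"""Two-mode wingbeat classification via 1-D Gaussian mixtures.

Small generalist birds fly intermittently: "normal" wingbeats around
17 Hz with a slightly longer downstroke mix with slower ~9.5 Hz beats
whose upstroke is roughly twice the downstroke.  Per bird, a
two-component Gaussian mixture f(x) = xi1 N(mu1, sigma1) + xi2 N(mu2,
sigma2) is fitted to the wingbeat frequency (and to the
downstroke/upstroke period ratio); a distribution counts as bimodal when
the component means are separated by more than twice the larger SD and
the smaller weight exceeds 0.1.  Beats are then labeled by the per-bird
frequency midpoint (the cohort separator is the across-bird mean of
those midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GMMConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class GMMFit:
    """Two-component 1-D Gaussian mixture, components sorted by mean."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    xi1: float
    xi2: float
    log_likelihood: float = np.nan
    n_iter: int = 0

    @property
    def separator(self) -> float:
        """Midpoint between the component means."""
        return 0.5 * (self.mu1 + self.mu2)

    @property
    def is_bimodal(self) -> bool:
        return bimodality_criterion(self)


def bimodality_criterion(fit: GMMFit) -> bool:
    """|mu1 - mu2| > 2 max(sigma1, sigma2) and min(xi1, xi2) > 0.1."""
    separation = abs(fit.mu1 - fit.mu2) > 2.0 * max(fit.sigma1, fit.sigma2)
    weight = min(fit.xi1, fit.xi2) > 0.1
    return bool(separation and weight)


def _log_gauss(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def fit_gmm2(
    x: np.ndarray,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> GMMFit:
    """Maximum-likelihood two-component mixture by EM.

    Deterministic: components are initialized at the 25th/75th sample
    percentiles with equal weights and the pooled SD.  A variance floor
    of 1e-6 var(x) guards against component collapse; per-iteration
    log-likelihood monotonicity is asserted.  ``seed`` is accepted for
    interface stability (the deterministic initialization ignores it).
    """
    del seed
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    total_var = float(np.var(x))
    if total_var <= 0:
        raise ValueError("degenerate sample: zero variance")
    var_floor = 1e-6 * total_var

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    var = np.array([total_var, total_var])
    xi = np.array([0.5, 0.5])

    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_resp = np.stack([
            np.log(xi[k]) + _log_gauss(x, mu[k], var[k]) for k in range(2)
        ])
        log_norm = np.logaddexp(log_resp[0], log_resp[1])
        ll = float(np.sum(log_norm))
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
            "EM log-likelihood decreased"
        )
        converged = ll - prev_ll < tol * max(1.0, abs(ll)) and n_iter > 1
        prev_ll = ll
        resp = np.exp(log_resp - log_norm)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        mu = (resp @ x) / nk
        var = np.array([
            float(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)
        ])
        var = np.maximum(var, var_floor)
        xi = nk / x.size
        if converged:
            break
    else:
        raise GMMConvergenceError(
            f"EM did not converge in {max_iter} iterations (ll={prev_ll:.6g}, "
            f"mu={mu}, sigma={np.sqrt(var)}, xi={xi})"
        )

    order = np.argsort(mu)
    mu, var, xi = mu[order], var[order], xi[order]
    return GMMFit(
        mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(np.sqrt(var[0])), sigma2=float(np.sqrt(var[1])),
        xi1=float(xi[0]), xi2=float(xi[1]),
        log_likelihood=prev_ll, n_iter=n_iter,
    )


def classify_beats(
    beats: pd.DataFrame,
    frequency_fits: dict[str, GMMFit],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label beats intermittent/normal and tabulate per-phase mode usage.

    ``beats`` needs columns bird, frequency and phase_label.  A beat is
    intermittent when its frequency is below the bird's frequency-fit
    midpoint (ties go to normal); birds whose fit fails the bimodality
    criterion get a single-mode label.  The usage table gives, per mode,
    the percentage of that mode's beats falling in each flight phase,
    computed per bird and then averaged across birds.
    """
    out = beats.copy()
    labels = []
    for _, row in out.iterrows():
        fit = frequency_fits.get(row["bird"])
        if fit is None or not bimodality_criterion(fit):
            labels.append("single_mode")
        elif row["frequency"] < fit.separator:
            labels.append("intermittent")
        else:
            labels.append("normal")
    out["mode"] = labels

    rows = []
    phases = ("before_turn", "during_turn", "after_turn")
    for mode in ("intermittent", "normal"):
        sub = out[out["mode"] == mode]
        if sub.empty:
            continue
        per_bird = []
        for _, grp in sub.groupby("bird"):
            total = len(grp)
            per_bird.append([100.0 * (grp["phase_label"] == ph).sum() / total
                             for ph in phases])
        arr = np.asarray(per_bird)
        for j, ph in enumerate(phases):
            rows.append({"mode": mode, "phase": ph,
                         "percent_mean": float(arr[:, j].mean()),
                         "percent_sd": float(arr[:, j].std(ddof=1)) if len(arr) > 1 else np.nan})
    return out, pd.DataFrame(rows)


def cross_bird_mode_summary(fits: dict[str, dict[str, GMMFit]]) -> pd.DataFrame:
    """Across-bird mean and sample SD of component means and midpoints.

    ``fits`` maps bird -> metric ("frequency", "ratio", ...) -> GMMFit.
    One row per (metric, quantity) with quantity in mu1, mu2, separator.
    """
    metrics = sorted({m for per_bird in fits.values() for m in per_bird})
    rows = []
    for metric in metrics:
        vals = {q: [] for q in ("mu1", "mu2", "separator")}
        for per_bird in fits.values():
            fit = per_bird.get(metric)
            if fit is None:
                continue
            vals["mu1"].append(fit.mu1)
            vals["mu2"].append(fit.mu2)
            vals["separator"].append(fit.separator)
        for q, v in vals.items():
            arr = np.asarray(v, dtype=float)
            rows.append({
                "metric": metric, "quantity": q, "n_birds": arr.size,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
            })
    return pd.DataFrame(rows)
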
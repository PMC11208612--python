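"""Model ranking, goodness-of-fit, and identifiability diagnostics.

Covers information-theoretic selection (AICc/QAICc, Akaike weights, 2-unit
model averaging), Cormack–Jolly–Seber (CJS) based goodness-of-fit — per-
primary deviance/df ĉ and RELEASE-style contingency components (TEST2 for
capture heterogeneity, TEST3 for survival heterogeneity) — and data-cloning
checks of parameter estimability.

ĉ here is deviance divided by degrees of freedom; the global value pools
components as Σχ²/Σdf (a ratio of sums, not a mean of ratios).  ĉ used for
QAICc is floored at 1; values above 3 indicate structural inadequacy rather
than mere overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .capture_data import CaptureMatrix, PooledMatrix

__all__ = [
    "aicc", "qaicc", "rank_models", "model_average",
    "CJSFit", "cjs_fit", "median_c_hat", "release_tests", "data_cloning",
]

C_HAT_FLOOR = 1.0
C_HAT_WARN = 3.0


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, K: int, ess: int) -> float:
    """Small-sample Akaike criterion: −2logL + 2K + 2K(K+1)/(ess−K−1)."""
    if ess <= K + 1:
        raise ValueError("effective sample size must exceed K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (ess - K - 1)


def qaicc(loglik: float, K: int, ess: int, c_hat: float) -> float:
    """Quasi-AICc: deviance divided by ĉ, one extra parameter for ĉ."""
    if c_hat < C_HAT_FLOOR:
        c_hat = C_HAT_FLOOR
    Kq = K + 1
    if ess <= Kq + 1:
        raise ValueError("effective sample size must exceed K + 2")
    return -2.0 * loglik / c_hat + 2.0 * Kq + 2.0 * Kq * (Kq + 1) / (
        ess - Kq - 1)


def rank_models(fits, c_hat: float | None = None,
                ess: int | None = None) -> pd.DataFrame:
    """Rank fits by AICc (or QAICc when ``c_hat`` is given).

    Fits must expose ``loglik``, ``K`` and ``n_individuals`` and be fits of
    the same data (equal individual counts).  Returns a table sorted by the
    criterion with Δ, Akaike weights, and the ≤2-unit averaging window flag.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit to rank")
    ns = {f.n_individuals for f in fits}
    if len(ns) != 1:
        raise ValueError("fits are not on the same data "
                         f"(individual counts {sorted(ns)})")
    n = ess if ess is not None else ns.pop()
    crit = []
    for f in fits:
        if c_hat is None:
            crit.append(aicc(f.loglik, f.K, n))
        else:
            crit.append(qaicc(f.loglik, f.K, n, c_hat))
    crit = np.asarray(crit)
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    names = [getattr(f, "structure", None) and f.structure.label()
             or f"model_{i}" for i, f in enumerate(fits)]
    df = pd.DataFrame({
        "model": names,
        "K": [f.K for f in fits],
        "criterion": crit,
        "delta": delta,
        "weight": w,
        "in_avg_window": delta <= 2.0,
    }).sort_values("criterion", kind="stable").reset_index(drop=True)
    df["delta"] = df["criterion"] - df["criterion"].iloc[0]
    return df


def model_average(fits, ess: int | None = None) -> pd.DataFrame:
    """Akaike-weight average of natural-scale estimates over a model window.

    Weights are renormalised over the supplied fits; unconditional SEs
    combine within-model variance and between-model spread:
    SE = sqrt( Σ w_i (se_i² + (θ̂_i − θ̄)²) ).  A single fit is returned
    unchanged (identity).  Parameters must share names across fits.
    """
    fits = list(fits)
    table = rank_models(fits, ess=ess)
    order = {name: i for i, name in enumerate(table["model"])}
    fits.sort(key=lambda f: order[f.structure.label()])
    w = table["weight"].to_numpy()
    w = w / w.sum()
    names = list(fits[0].natural_estimates())
    for f in fits[1:]:
        if list(f.natural_estimates()) != names:
            raise ValueError("parameters not comparable across structures")
    est = np.array([[f.natural_estimates()[k] for k in names] for f in fits])
    ses = np.array([[f.natural_ses()[k] for k in names] for f in fits])
    avg = w @ est
    se_unc = np.sqrt(w @ (ses ** 2 + (est - avg) ** 2))
    return pd.DataFrame({"parameter": names, "estimate": avg,
                         "se_unconditional": se_unc})


# ---------------------------------------------------------------------------
# CJS fitting and deviance-based c-hat
# ---------------------------------------------------------------------------

def _as_binary(data) -> np.ndarray:
    if isinstance(data, PooledMatrix):
        return np.asarray(data.detections)
    if isinstance(data, CaptureMatrix):
        return np.asarray(data.detections)
    return np.asarray(data)


def _reduced_m_array(det: np.ndarray):
    """Releases, first-recapture counts and never-reseen counts."""
    T = det.shape[1]
    releases = det.sum(axis=0).astype(int)
    m = np.zeros((T, T), dtype=int)
    never = np.zeros(T, dtype=int)
    for row in det:
        occ = np.flatnonzero(row)
        if occ.size == 0:
            continue
        for i, j in zip(occ[:-1], occ[1:]):
            m[i, j] += 1
        never[occ[-1]] += 1
    return releases, m, never


@dataclass
class CJSFit:
    phi: np.ndarray       # length T-1
    p: np.ndarray         # length T-1, detection at occasions 2..T
    loglik: float
    loglik_saturated: float
    deviance: float
    df: int
    c_hat: float
    converged: bool
    n_released: int


def _cjs_cell_probs(phi: np.ndarray, p: np.ndarray, T: int) -> np.ndarray:
    """π[i, j] = Pr(next detection at occasion j | released at i)."""
    pi = np.zeros((T, T))
    for i in range(T - 1):
        surv = 1.0
        for j in range(i + 1, T):
            surv *= phi[j - 1]
            miss = np.prod(1.0 - p[i:j - 1]) if j - 1 > i else 1.0
            pi[i, j] = surv * miss * p[j - 1]
    return pi


def cjs_fit(data, tol: float = 1e-10) -> CJSFit:
    """Time-varying CJS fit with deviance against the saturated multinomial.

    ``data`` is a binary detection matrix (or Pooled/CaptureMatrix); rows
    without detections are ignored.  The model is conditional on first
    release; the last survival and detection parameters appear only as a
    product, so the estimable parameter count is 2(T−1) − 1.
    """
    det = _as_binary(data)
    det = det[det.sum(axis=1) > 0]
    T = det.shape[1]
    if T < 3:
        raise ValueError("time-varying CJS needs >= 3 occasions")
    releases, m, never = _reduced_m_array(det)
    # cohort releases for the multinomial exclude the final occasion
    def nll(x: np.ndarray) -> float:
        phi = 1.0 / (1.0 + np.exp(-x[:T - 1]))
        p = 1.0 / (1.0 + np.exp(-x[T - 1:]))
        pi = _cjs_cell_probs(phi, p, T)
        ll = 0.0
        for i in range(T - 1):
            if releases[i] == 0:
                continue
            chi = 1.0 - pi[i, i + 1:].sum()
            with np.errstate(divide="ignore"):
                ll += (m[i, i + 1:] * np.log(np.clip(pi[i, i + 1:], 1e-300,
                                                     None))).sum()
                ll += never[i] * np.log(max(chi, 1e-300))
        return -ll

    x0 = np.zeros(2 * (T - 1))
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": tol})
    phi = 1.0 / (1.0 + np.exp(-res.x[:T - 1]))
    p = 1.0 / (1.0 + np.exp(-res.x[T - 1:]))

    # saturated multinomial log-likelihood over the same cells
    ll_sat = 0.0
    n_cells_minus1 = 0
    for i in range(T - 1):
        R = int(releases[i])
        if R == 0:
            continue
        counts = np.concatenate([m[i, i + 1:], [never[i]]])
        nz = counts[counts > 0]
        ll_sat += (nz * np.log(nz / R)).sum()
        n_cells_minus1 += len(counts) - 1
    deviance = 2.0 * (ll_sat + res.fun)
    K_est = 2 * (T - 1) - 1
    df = max(n_cells_minus1 - K_est, 0)
    c_hat = deviance / df if df > 0 else float("nan")
    return CJSFit(phi=phi, p=p, loglik=-res.fun, loglik_saturated=ll_sat,
                  deviance=max(deviance, 0.0), df=df, c_hat=c_hat,
                  converged=bool(res.success),
                  n_released=int(releases[:-1].sum()))


def median_c_hat(matrix: CaptureMatrix) -> pd.DataFrame:
    """Per-primary CJS deviance/df rows plus the pooled global ĉ.

    Each primary's secondary occasions are treated as a CJS time series; the
    global ĉ is the ratio of summed deviances to summed df, appended as a
    final ``global`` row.  Primaries with fewer than 3 secondaries or zero df
    are excluded with a warning row count.
    """
    rows = []
    for t in range(matrix.design.n_primary):
        label = matrix.design.primary_labels[t]
        block = matrix.primary_block(t)
        if block.shape[1] < 3:
            continue
        fit = cjs_fit(block)
        if fit.df == 0:
            continue
        rows.append({"period": label, "deviance": fit.deviance,
                     "df": fit.df, "c_hat": fit.deviance / fit.df})
    out = pd.DataFrame(rows)
    if not out.empty:
        tot_dev, tot_df = out["deviance"].sum(), int(out["df"].sum())
        out = pd.concat([out, pd.DataFrame([{
            "period": "global", "deviance": tot_dev, "df": tot_df,
            "c_hat": tot_dev / tot_df if tot_df else float("nan")}])],
            ignore_index=True)
    return out


def global_c_hat(chi2_components, df_components) -> float:
    """Pooled ĉ = Σχ² / Σdf (ratio of sums)."""
    chi2 = float(np.sum(chi2_components))
    df = float(np.sum(df_components))
    if df <= 0:
        raise ValueError("total df must be positive")
    return chi2 / df


# ---------------------------------------------------------------------------
# RELEASE-style contingency tests
# ---------------------------------------------------------------------------

def _chi2_2xc(table: np.ndarray, min_expected: float = 2.0):
    """Pearson χ² for a 2×c table, pooling sparse columns (expected < min).

    Columns are pooled right-to-left until all expected counts reach the
    threshold or the table collapses (then χ² = df = 0).
    """
    tab = np.asarray(table, dtype=float)
    tab = tab[:, tab.sum(axis=0) > 0]
    while tab.shape[1] >= 2:
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        if (exp >= min_expected).all() or tab.shape[1] == 2:
            break
        j = int(np.argmin(exp.min(axis=0)))
        k = j - 1 if j == tab.shape[1] - 1 else j + 1
        tab[:, k] += tab[:, j]
        tab = np.delete(tab, j, axis=1)
    if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
        return 0.0, 0
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if (exp < min_expected).any():
        return 0.0, 0
    chi2 = float(((tab - exp) ** 2 / exp).sum())
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return chi2, df


def release_tests(pooled: PooledMatrix) -> dict:
    """TEST2 / TEST3 heterogeneity components on season-pooled histories.

    Operates on the pooled capture histories (the reduced m-array alone does
    not retain the newly-vs-previously-marked split the sub-tables need).

    * TEST3.SR (survival): at each interior occasion, newly vs previously
      marked animals × ever seen again or not.
    * TEST3.Sm: among those seen again, newly vs previously marked × next
      seen at the following occasion vs later.
    * TEST2.CT (capture): among animals known alive across occasion i (seen
      at-or-before and after), seen at i vs not × next detection at i+1 vs
      later.

    Sub-table χ² values are summed with sparse cells pooled (expected < 2).
    """
    det = _as_binary(pooled)
    det = det[det.sum(axis=1) > 0]
    T = det.shape[1]
    if T < 3:
        raise ValueError("need >= 3 pooled occasions")
    first = np.argmax(det, axis=1)
    chi2_t2 = df_t2 = 0.0
    chi2_t3 = df_t3 = 0.0
    for i in range(1, T - 1):
        seen_i = det[:, i] == 1
        seen_after = det[:, i + 1:].sum(axis=1) > 0
        new_i = first == i
        # TEST3.SR
        sr = np.array([
            [np.sum(new_i & seen_i & seen_after),
             np.sum(new_i & seen_i & ~seen_after)],
            [np.sum(~new_i & seen_i & seen_after),
             np.sum(~new_i & seen_i & ~seen_after)],
        ])
        c, d = _chi2_2xc(sr)
        chi2_t3, df_t3 = chi2_t3 + c, df_t3 + d
        # TEST3.Sm: next sighting at i+1 vs later
        next_at = det[:, i + 1] == 1
        sm = np.array([
            [np.sum(new_i & seen_i & seen_after & next_at),
             np.sum(new_i & seen_i & seen_after & ~next_at)],
            [np.sum(~new_i & seen_i & seen_after & next_at),
             np.sum(~new_i & seen_i & seen_after & ~next_at)],
        ])
        c, d = _chi2_2xc(sm)
        chi2_t3, df_t3 = chi2_t3 + c, df_t3 + d
        # TEST2.CT: known alive across i
        seen_before = (det[:, :i + 1].sum(axis=1) > 0)
        alive = seen_before & seen_after
        ct = np.array([
            [np.sum(alive & seen_i & next_at),
             np.sum(alive & seen_i & ~next_at)],
            [np.sum(alive & ~seen_i & next_at),
             np.sum(alive & ~seen_i & ~next_at)],
        ])
        c, d = _chi2_2xc(ct)
        chi2_t2, df_t2 = chi2_t2 + c, df_t2 + d
    out = {
        "test2": {"chi2": chi2_t2, "df": int(df_t2),
                  "c_hat": chi2_t2 / df_t2 if df_t2 else float("nan")},
        "test3": {"chi2": chi2_t3, "df": int(df_t3),
                  "c_hat": chi2_t3 / df_t3 if df_t3 else float("nan")},
    }
    return out


# ---------------------------------------------------------------------------
# data cloning
# ---------------------------------------------------------------------------

def data_cloning(matrix: CaptureMatrix, structure, K_clones: int = 100,
                 seed: int = 0, base_fit=None,
                 ratio_tolerance: float = 0.25) -> pd.DataFrame:
    """Estimability diagnostics by K-fold data cloning.

    Refits the model with every history weighted K times.  Point estimates
    should be unchanged; the information matrix scales by K, so SEs of
    estimable parameters shrink by 1/sqrt(K).  Both the 1/sqrt(K) and the
    1/K reference lines are reported; the estimability verdict compares the
    observed ratio with 1/sqrt(K) within ``ratio_tolerance`` (relative).
    Boundary parameters are flagged rather than judged.
    """
    from .msord import fit_msord

    if K_clones < 2:
        raise ValueError("need K_clones >= 2")
    if base_fit is None:
        base_fit = fit_msord(matrix, structure, seed=seed)
    freq = np.full(matrix.n_individuals, float(K_clones))
    clone_fit = fit_msord(matrix, structure, seed=seed, freq=freq)

    est0, ses0 = base_fit.natural_estimates(), base_fit.natural_ses()
    est1, ses1 = clone_fit.natural_estimates(), clone_fit.natural_ses()
    expected = 1.0 / np.sqrt(K_clones)
    rows = []
    for name in est0:
        se0, se1 = ses0[name], ses1[name]
        ratio = se1 / se0 if se0 > 0 else float("nan")
        at_boundary = name in base_fit.boundary_flags
        if at_boundary or not np.isfinite(ratio):
            verdict = "flagged"
        elif abs(ratio - expected) <= ratio_tolerance * expected:
            verdict = "estimable"
        else:
            verdict = "non-estimable"
        rows.append({
            "parameter": name, "estimate": est0[name],
            "estimate_cloned": est1[name], "se": se0, "se_cloned": se1,
            "se_ratio": ratio, "expected_sqrt": expected,
            "expected_linear": 1.0 / K_clones, "verdict": verdict,
        })
    return pd.DataFrame(rows)
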
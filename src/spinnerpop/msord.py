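"""Multi-state open robust design (MSORD) likelihood and fitting.

The model tracks marked animals across T primary periods (seasons), each with
J_t secondary occasions (surveys).  Between primaries an animal survives with
apparent survival S and moves between an observable state P (present in the
study area) and an unobservable temporary-emigrant state E with Markovian
transition probabilities ψ^{P→E}, ψ^{E→E} (random emigration ties the two;
"no emigration" fixes both to 0).  Within a primary an animal in state P
enters the area once at secondary occasion a with probability pent_a,
persists occasion-to-occasion with probability φ_j, leaves once, and while
present is detected with probability p_j.  The within-primary sub-model is
therefore an open entry/exit ("staggered arrival and departure") model; the
availability window [a, d] has probability

    pent_a · Π_{j=a}^{d-1} φ_j · (1 − φ_d)     (no departure factor at d = J).

The likelihood is conditional on first encounter: the primary of first
detection contributes Pr(ω)/p*, where p* is the probability of ≥1 detection
for an animal present in the primary; subsequent primaries run a forward
recursion over {P, E, dead}.  Detection equals recapture probability (photo
identification elicits no trap response), so a single p applies throughout.

Probabilities are estimated on link scales (logit; multinomial logit for each
pent vector) by quasi-Newton maximisation with multi-start; SEs come from the
inverse observed-information matrix propagated through the links.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .capture_data import CaptureMatrix, StudyDesign

__all__ = [
    "ModelStructure", "MSORDParams", "MSORDFit",
    "window_masses", "within_primary_prob", "pstar", "emission_probs",
    "history_loglik", "msord_loglik", "fit_msord",
    "derive_abundance", "derived_transitions", "residence_time",
]

_VAR_LEVELS = ("constant", "season", "season.day")


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelStructure:
    """Which parameters vary by what, and the emigration regime.

    Variation levels: ``constant`` (one value, shared), ``season`` (one per
    primary) and ``season.day`` (one per secondary occasion).  For entry
    probabilities, ``constant`` means one simplex vector shared across
    primaries, ``season.day`` one vector per primary, and ``season`` — a
    single shared value per cell within each primary — collapses to uniform
    entry under the sum-to-one constraint (zero free cells).

    ``psi_time`` lets the emigration probabilities vary by inter-primary
    interval (the regime named "Markovian" in published model tables).
    """

    s: str = "constant"
    p: str = "constant"
    pent: str = "season.day"
    phi: str = "season.day"
    emigration: str = "markovian"
    psi_time: bool = True

    def __post_init__(self) -> None:
        for name, lvl in (("s", self.s), ("p", self.p), ("pent", self.pent),
                          ("phi", self.phi)):
            if lvl not in _VAR_LEVELS:
                raise ValueError(f"unknown variation {lvl!r} for {name}")
        if self.s == "season.day":
            raise ValueError("survival varies at most by season")
        if self.emigration not in ("markovian", "random", "none"):
            raise ValueError(f"unknown emigration regime {self.emigration!r}")

    @classmethod
    def from_string(cls, spec: str) -> "ModelStructure":
        """Parse model notation like ``S(.) p(.) pent(season.day)
        phi(season.day) psi(Markovian)``."""
        tokens = dict(re.findall(r"(\w+)\(([^)]*)\)", spec))
        level = {".": "constant", "season": "season", "t": "season.day",
                 "season.day": "season.day", "season.survey": "season.day"}

        def var(key: str, default: str) -> str:
            raw = tokens.get(key, default).strip()
            if raw not in level:
                raise ValueError(f"unknown variation {raw!r} for {key}")
            return level[raw]

        psi_raw = tokens.get("psi", "Markovian").strip().lower()
        parts = [p for p in re.split(r"[.,]", psi_raw) if p]
        regime = parts[0] if parts else "markovian"
        if regime not in ("markovian", "random", "none"):
            raise ValueError(f"unknown emigration regime {psi_raw!r}")
        psi_time = "constant" not in parts[1:] and regime != "none"
        if "phi" not in tokens and "varphi" in tokens:
            tokens["phi"] = tokens["varphi"]
        return cls(s=var("S", "."), p=var("p", "."),
                   pent=var("pent", "season.day"),
                   phi=var("phi", "season.day"),
                   emigration=regime, psi_time=psi_time)

    def label(self) -> str:
        disp = {"constant": ".", "season": "season", "season.day": "season.day"}
        psi = {"markovian": "Markovian", "random": "random", "none": "none"}[
            self.emigration]
        if self.emigration != "none" and not self.psi_time:
            psi += ",constant"
        return (f"S({disp[self.s]}) p({disp[self.p]}) pent({disp[self.pent]}) "
                f"phi({disp[self.phi]}) psi({psi})")


@dataclass
class MSORDParams:
    """Natural-scale parameters for a given design.

    ``S``, ``psi_PE``, ``psi_EE`` have one entry per inter-primary interval
    (length T−1); ``p``, ``pent``, ``phi`` are per-primary arrays of lengths
    J_t, J_t and J_t−1.  Each ``pent`` vector sums to one.
    """

    S: np.ndarray
    p: list[np.ndarray]
    pent: list[np.ndarray]
    phi: list[np.ndarray]
    psi_PE: np.ndarray
    psi_EE: np.ndarray

    def validate(self, design: StudyDesign) -> None:
        T = design.n_primary
        if len(self.S) != T - 1 or len(self.psi_PE) != T - 1 \
                or len(self.psi_EE) != T - 1:
            raise ValueError("interval-parameter lengths must be T-1")
        for t, J in enumerate(design.secondaries_per_primary):
            if len(self.p[t]) != J or len(self.pent[t]) != J \
                    or len(self.phi[t]) != max(J - 1, 0):
                raise ValueError(f"primary {t + 1}: parameter lengths do not "
                                 "match design")
            if not np.isclose(self.pent[t].sum(), 1.0, atol=1e-8):
                raise ValueError(f"primary {t + 1}: pent must sum to 1")
        for arr in ([self.S, self.psi_PE, self.psi_EE] + self.p + self.pent
                    + self.phi):
            a = np.asarray(arr, dtype=float)
            if ((a < 0) | (a > 1)).any():
                raise ValueError("all parameters must lie in [0, 1]")


# ---------------------------------------------------------------------------
# within-primary open sub-model
# ---------------------------------------------------------------------------

def window_masses(pent: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Probability of each availability window [a, d] (0-based, upper tri).

    Masses over all windows sum to one for any valid (pent, φ).
    """
    pent = np.asarray(pent, dtype=float)
    phi = np.asarray(phi, dtype=float)
    J = len(pent)
    M = np.zeros((J, J))
    for a in range(J):
        stay = pent[a]
        for d in range(a, J):
            if d > a:
                stay *= phi[d - 1]
            depart = (1.0 - phi[d]) if d < J - 1 else 1.0
            M[a, d] = stay * depart
    return M


def emission_probs(block: np.ndarray, pent: np.ndarray, phi: np.ndarray,
                   p: np.ndarray) -> np.ndarray:
    """Pr(detection rows | state P) for an (n, J) block of 0/1 rows."""
    X = np.asarray(block, dtype=float)
    p = np.asarray(p, dtype=float)
    n, J = X.shape
    M = window_masses(pent, phi)
    L = X * p + (1.0 - X) * (1.0 - p)      # per-occasion Bernoulli terms
    cum_det = np.cumsum(X, axis=1)
    tot_det = cum_det[:, -1]
    w = np.zeros(n)
    for a in range(J):
        det_before = cum_det[:, a - 1] if a > 0 else np.zeros(n)
        inside = np.ones(n)
        for d in range(a, J):
            inside = inside * L[:, d]
            if M[a, d] == 0.0:
                continue
            outside_ok = (det_before == 0) & (tot_det - cum_det[:, d] == 0)
            w += M[a, d] * outside_ok * inside
    return w


def within_primary_prob(omega: Sequence[int], pent: Sequence[float],
                        phi: Sequence[float], p: Sequence[float]) -> float:
    """Probability of one detection vector for an animal in state P."""
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    pent = np.asarray(pent, dtype=float)
    if not np.isclose(pent.sum(), 1.0, atol=1e-6):
        raise ValueError("pent must sum to 1")
    if omega.shape[1] != len(pent):
        raise ValueError("omega length must match pent length")
    return float(emission_probs(omega, pent, np.asarray(phi), np.asarray(p))[0])


def pstar(pent: Sequence[float], phi: Sequence[float],
          p: Sequence[float]) -> float:
    """Probability of ≥1 detection during the primary for a present animal."""
    zeros = np.zeros(len(np.asarray(pent)))
    return 1.0 - within_primary_prob(zeros, pent, phi, p)


# ---------------------------------------------------------------------------
# full likelihood
# ---------------------------------------------------------------------------

def _pattern_cache(matrix: CaptureMatrix):
    """Per-primary unique detection patterns, cached on the matrix.

    Emissions depend only on the within-primary pattern, so duplicate rows
    are collapsed once; an all-zero row is appended to each pattern set so
    p* falls out of the same emission computation.
    """
    cache = getattr(matrix, "_msord_patterns", None)
    if cache is None:
        cache = []
        for t in range(matrix.design.n_primary):
            block = matrix.primary_block(t)
            uniq, inv = np.unique(block, axis=0, return_inverse=True)
            aug = np.vstack([uniq, np.zeros((1, block.shape[1]),
                                            dtype=uniq.dtype)])
            cache.append((aug, inv, block.sum(axis=1) == 0))
        matrix._msord_patterns = cache
    return cache


def _per_primary_terms(matrix: CaptureMatrix, params: MSORDParams):
    """Emission probabilities w_t(ω_i), zero-row flags and p*_t per primary."""
    T = matrix.design.n_primary
    w = np.empty((matrix.n_individuals, T))
    zero = np.empty((matrix.n_individuals, T), dtype=bool)
    ps = np.empty(T)
    for t, (aug, inv, zero_t) in enumerate(_pattern_cache(matrix)):
        w_aug = emission_probs(aug, params.pent[t], params.phi[t],
                               params.p[t])
        w[:, t] = w_aug[inv]
        ps[t] = 1.0 - w_aug[-1]
        zero[:, t] = zero_t
    return w, zero, ps


def msord_loglik(matrix: CaptureMatrix, params: MSORDParams) -> float:
    """Total conditional-on-first-encounter log-likelihood."""
    params.validate(matrix.design)
    ll = _loglik_vector(matrix, params)
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(
            f"non-finite log-likelihood for history index {bad} "
            f"({''.join(map(str, matrix.detections[bad]))})")
    return float(ll.sum())


def _loglik_vector(matrix: CaptureMatrix, params: MSORDParams) -> np.ndarray:
    T = matrix.design.n_primary
    n = matrix.n_individuals
    w, zero, ps = _per_primary_terms(matrix, params)
    first = np.argmax(~zero, axis=1)
    alpha_P = np.zeros(n)
    alpha_E = np.zeros(n)
    alpha_D = np.zeros(n)
    for t in range(T):
        if t > 0:
            S = params.S[t - 1]
            pPE, pEE = params.psi_PE[t - 1], params.psi_EE[t - 1]
            P_next = S * ((1.0 - pPE) * alpha_P + (1.0 - pEE) * alpha_E)
            E_next = S * (pPE * alpha_P + pEE * alpha_E)
            D_next = (1.0 - S) * (alpha_P + alpha_E) + alpha_D
            alpha_P = P_next * w[:, t]
            alpha_E = E_next * zero[:, t]
            alpha_D = D_next * zero[:, t]
        new = first == t
        if new.any():
            alpha_P = np.where(new, w[:, t] / ps[t], alpha_P)
            alpha_E = np.where(new, 0.0, alpha_E)
            alpha_D = np.where(new, 0.0, alpha_D)
    with np.errstate(divide="ignore"):
        return np.log(alpha_P + alpha_E + alpha_D)


def history_loglik(history: Sequence[int], params: MSORDParams,
                   design: StudyDesign) -> float:
    """Log-probability of a single capture history (must have ≥1 detection)."""
    hist = np.asarray(history, dtype=np.int8).reshape(1, -1)
    if hist.sum() == 0:
        raise ValueError("history must contain at least one detection")
    matrix = CaptureMatrix(["h"], hist, design)
    params.validate(design)
    return float(_loglik_vector(matrix, params)[0])


# ---------------------------------------------------------------------------
# link-scale parameterisation
# ---------------------------------------------------------------------------

def _logit(x):
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return np.log(x / (1 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class ParamLayout:
    """Packing of a :class:`ModelStructure` into a free link-scale vector.

    Probabilities use logit links; each free entry-probability vector uses a
    multinomial logit with its first cell as reference.
    """

    def __init__(self, structure: ModelStructure, design: StudyDesign):
        self.structure = structure
        self.design = design
        T = design.n_primary
        Js = design.secondaries_per_primary
        if structure.pent == "constant" and len(set(Js)) > 1:
            raise ValueError("shared pent vector needs a balanced design")
        blocks: list[tuple[str, int]] = []
        blocks.append(("S", 1 if structure.s == "constant" else T - 1))
        blocks.append(("p", {"constant": 1, "season": T,
                             "season.day": sum(Js)}[structure.p]))
        blocks.append(("pent", {"constant": Js[0] - 1, "season": 0,
                                "season.day": sum(J - 1 for J in Js)}
                       [structure.pent]))
        n_phi_cells = sum(J - 1 for J in Js)
        blocks.append(("phi", 0 if n_phi_cells == 0 else
                       {"constant": 1, "season": T,
                        "season.day": n_phi_cells}[structure.phi]))
        n_psi = (T - 1) if structure.psi_time else 1
        if structure.emigration == "none":
            blocks.append(("psi", 0))
        elif structure.emigration == "random":
            blocks.append(("psi", n_psi))
        else:
            blocks.append(("psi", 2 * n_psi))
        self.blocks = blocks
        self.n_free = sum(sz for _, sz in blocks)

    def _split(self, x: np.ndarray) -> dict[str, np.ndarray]:
        out, i = {}, 0
        for name, size in self.blocks:
            out[name] = x[i:i + size]
            i += size
        return out

    def unpack(self, x: np.ndarray) -> MSORDParams:
        st, design = self.structure, self.design
        T = design.n_primary
        Js = design.secondaries_per_primary
        b = self._split(np.asarray(x, dtype=float))

        S = _expit(b["S"])
        S = np.repeat(S, T - 1) if st.s == "constant" else S

        if st.p == "constant":
            p = [np.full(J, _expit(b["p"][0])) for J in Js]
        elif st.p == "season":
            p = [np.full(Js[t], _expit(b["p"][t])) for t in range(T)]
        else:
            off = np.concatenate([[0], np.cumsum(Js)])
            p = [_expit(b["p"][off[t]:off[t + 1]]) for t in range(T)]

        def simplex(eta: np.ndarray) -> np.ndarray:
            z = np.concatenate([[0.0], eta])
            z = np.exp(z - z.max())
            return z / z.sum()

        if st.pent == "constant":
            shared = simplex(b["pent"])
            pent = [shared.copy() for _ in range(T)]
        elif st.pent == "season":
            pent = [np.full(J, 1.0 / J) for J in Js]
        else:
            off = np.concatenate([[0], np.cumsum([J - 1 for J in Js])])
            pent = [simplex(b["pent"][off[t]:off[t + 1]]) for t in range(T)]

        if b["phi"].size == 0:
            phi = [np.zeros(max(J - 1, 0)) for J in Js]
        elif st.phi == "constant":
            phi = [np.full(max(J - 1, 0), _expit(b["phi"][0])) for J in Js]
        elif st.phi == "season":
            phi = [np.full(max(Js[t] - 1, 0), _expit(b["phi"][t]))
                   for t in range(T)]
        else:
            off = np.concatenate([[0], np.cumsum([J - 1 for J in Js])])
            phi = [_expit(b["phi"][off[t]:off[t + 1]]) for t in range(T)]

        n_psi = (T - 1) if st.psi_time else 1
        if st.emigration == "none":
            psi_PE = np.zeros(T - 1)
            psi_EE = np.zeros(T - 1)
        elif st.emigration == "random":
            shared_psi = _expit(b["psi"])
            psi_PE = psi_EE = (shared_psi if st.psi_time
                               else np.repeat(shared_psi, T - 1))
        else:
            pe = _expit(b["psi"][:n_psi])
            ee = _expit(b["psi"][n_psi:])
            psi_PE = pe if st.psi_time else np.repeat(pe, T - 1)
            psi_EE = ee if st.psi_time else np.repeat(ee, T - 1)
        return MSORDParams(S=S, p=p, pent=pent, phi=phi,
                           psi_PE=psi_PE, psi_EE=np.asarray(psi_EE))

    def default_start(self) -> np.ndarray:
        """A mild interior starting point (S high, p moderate, ψ moderate)."""
        x = np.zeros(self.n_free)
        b, i = {}, 0
        for name, size in self.blocks:
            if name == "S":
                x[i:i + size] = _logit(0.9)
            elif name == "p":
                x[i:i + size] = _logit(0.3)
            elif name == "phi":
                x[i:i + size] = _logit(0.7)
            elif name == "psi":
                x[i:i + size] = _logit(0.3)
            i += size
        return x

    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        """Flattened natural-scale parameters (tied entries expanded)."""
        p = self.unpack(x)
        return np.concatenate([p.S] + p.p + p.pent + p.phi
                              + [p.psi_PE, p.psi_EE])

    def natural_names(self) -> list[str]:
        T = self.design.n_primary
        Js = self.design.secondaries_per_primary
        names = [f"S[{t + 1}->{t + 2}]" for t in range(T - 1)]
        names += [f"p[{t + 1},{j + 1}]" for t in range(T)
                  for j in range(Js[t])]
        names += [f"pent[{t + 1},{j + 1}]" for t in range(T)
                  for j in range(Js[t])]
        names += [f"phi[{t + 1},{j + 1}]" for t in range(T)
                  for j in range(Js[t] - 1)]
        names += [f"psi_PE[{t + 1}->{t + 2}]" for t in range(T - 1)]
        names += [f"psi_EE[{t + 1}->{t + 2}]" for t in range(T - 1)]
        return names


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MSORDFit:
    structure: ModelStructure
    design: StudyDesign
    layout: ParamLayout
    x: np.ndarray                       # link-scale MLE
    params: MSORDParams                 # natural scale
    cov_link: np.ndarray | None
    loglik: float
    K: int
    n_individuals: int
    aicc: float
    converged: bool
    n_restarts_used: int
    boundary_flags: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def natural_estimates(self) -> dict[str, float]:
        vec = self.layout.natural_vector(self.x)
        return dict(zip(self.layout.natural_names(), vec))

    def natural_ses(self) -> dict[str, float]:
        if self.cov_link is None:
            return {k: float("nan") for k in self.layout.natural_names()}
        J = _num_jacobian(self.layout.natural_vector, self.x)
        var = np.einsum("ij,jk,ik->i", J, self.cov_link, J)
        return dict(zip(self.layout.natural_names(),
                        np.sqrt(np.clip(var, 0.0, None))))


def _num_jacobian(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x))
    J = np.empty((len(f0), len(x)))
    for k in range(len(x)):
        dx = np.zeros_like(x)
        dx[k] = eps
        J[:, k] = (np.asarray(f(x + dx)) - np.asarray(f(x - dx))) / (2 * eps)
    return J


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = eps
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps ** 2)
    return H


def aicc_value(loglik: float, K: int, ess: int) -> float:
    if ess <= K + 1:
        raise ValueError("effective sample size must exceed K + 1")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (ess - K - 1)


def fit_msord(matrix: CaptureMatrix, structure: ModelStructure,
              n_restarts: int = 3, seed: int = 0, ess: int | None = None,
              compute_cov: bool = True, tol: float = 1e-8,
              freq: np.ndarray | None = None) -> MSORDFit:
    """Maximum-likelihood fit of an MSORD structure.

    ``freq`` optionally weights each history (used for data cloning).  The
    effective sample size for AICc defaults to the number of histories.
    Restarts perturb the default start; the best converged optimum wins.
    """
    layout = ParamLayout(structure, matrix.design)
    weights = np.ones(matrix.n_individuals) if freq is None \
        else np.asarray(freq, dtype=float)

    def nll(x: np.ndarray) -> float:
        try:
            params = layout.unpack(x)
            ll = _loglik_vector(matrix, params)
        except (FloatingPointError, ValueError):
            return 1e12
        if not np.isfinite(ll).all():
            return 1e12
        return -float(weights @ ll)

    rng = np.random.default_rng(seed)
    starts = [layout.default_start()]
    starts += [layout.default_start() + rng.normal(0, 0.7, layout.n_free)
               for _ in range(max(n_restarts - 1, 0))]
    best, n_used = None, 0
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": tol})
        n_used += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None
    converged = bool(best.success) and best.fun < 1e11
    params = layout.unpack(best.x)
    loglik = -best.fun

    cov = None
    messages: list[str] = []
    if compute_cov and converged and layout.n_free > 0:
        H = _num_hessian(nll, best.x)
        try:
            cov = np.linalg.inv(H)
            if (np.diag(cov) < 0).any():
                messages.append("non-positive-definite Hessian; SEs unreliable")
        except np.linalg.LinAlgError:
            messages.append("singular Hessian; no covariance")
            cov = None

    boundary = [name for name, val in zip(layout.natural_names(),
                                          layout.natural_vector(best.x))
                if val < 1e-4 or val > 1 - 1e-4]
    n = int(weights.sum())
    K = layout.n_free
    fit = MSORDFit(
        structure=structure, design=matrix.design, layout=layout,
        x=best.x, params=params, cov_link=cov, loglik=loglik, K=K,
        n_individuals=n, aicc=aicc_value(loglik, K, ess or n),
        converged=converged, n_restarts_used=n_used,
        boundary_flags=boundary, messages=messages)
    return fit


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def derive_abundance(fit: MSORDFit, matrix: CaptureMatrix):
    """Per-primary marked abundance N̂_m,t = n_t / p̂*_t with delta-method SE.

    Two SE variants are returned: ``se_model`` propagates var(p̂*) only;
    ``se_total`` adds the Horvitz–Thompson binomial component
    n_t(1−p̂*)/p̂*².
    """
    import pandas as pd
    if not fit.converged:
        raise ValueError("abundance requires a converged fit")
    design = matrix.design
    T = design.n_primary
    rows = []
    for t in range(T):
        n_t = int((matrix.primary_block(t).sum(axis=1) > 0).sum())

        def pstar_t(x: np.ndarray, t=t) -> np.ndarray:
            p = fit.layout.unpack(x)
            return np.array([1.0 - emission_probs(
                np.zeros((1, design.secondaries_per_primary[t])),
                p.pent[t], p.phi[t], p.p[t])[0]])

        ps = float(pstar_t(fit.x)[0])
        if ps < 1e-8:
            raise FloatingPointError(
                f"p* ~ 0 in primary {t + 1}; abundance undefined")
        var_ps = 0.0
        if fit.cov_link is not None:
            g = _num_jacobian(pstar_t, fit.x)[0]
            var_ps = float(g @ fit.cov_link @ g)
        var_model = (n_t / ps ** 2) ** 2 * max(var_ps, 0.0)
        var_binom = n_t * (1.0 - ps) / ps ** 2
        rows.append({
            "period": design.primary_labels[t], "n": n_t, "pstar": ps,
            "N_m": n_t / ps, "se_model": np.sqrt(var_model),
            "se_total": np.sqrt(var_model + var_binom),
        })
    return pd.DataFrame(rows)


def derived_transitions(fit: MSORDFit):
    """Complement transition probabilities per interval.

    ψ^{P→P} = 1 − ψ^{P→E} and ψ^{E→P} = 1 − ψ^{E→E}; delta-method SEs equal
    the source SEs.
    """
    import pandas as pd
    if fit.structure.emigration == "none":
        raise ValueError("no transition probabilities in a no-emigration model")
    ses = fit.natural_ses()
    T = fit.design.n_primary
    rows = []
    for t in range(T - 1):
        pe, ee = fit.params.psi_PE[t], fit.params.psi_EE[t]
        rows.append({
            "interval": f"{fit.design.primary_labels[t]} -> "
                        f"{fit.design.primary_labels[t + 1]}",
            "psi_PE": pe, "se_psi_PE": ses[f"psi_PE[{t + 1}->{t + 2}]"],
            "psi_EE": ee, "se_psi_EE": ses[f"psi_EE[{t + 1}->{t + 2}]"],
            "psi_PP": 1.0 - pe, "se_psi_PP": ses[f"psi_PE[{t + 1}->{t + 2}]"],
            "psi_EP": 1.0 - ee, "se_psi_EP": ses[f"psi_EE[{t + 1}->{t + 2}]"],
        })
    return pd.DataFrame(rows)


def residence_time(fit: MSORDFit) -> np.ndarray:
    """Expected number of secondary occasions present per primary.

    E[d − a + 1] under the fitted entry/persistence window distribution.
    """
    out = np.empty(fit.design.n_primary)
    for t in range(fit.design.n_primary):
        M = window_masses(fit.params.pent[t], fit.params.phi[t])
        J = M.shape[0]
        lengths = np.abs(np.subtract.outer(np.arange(J), np.arange(J))) + 1
        out[t] = float((M * lengths).sum())
    return out
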
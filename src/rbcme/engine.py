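"""Compiled numerical core: propensity encoding, SSA and matrix-exponential
kernels.

Networks are compiled to flat numeric arrays so that the stochastic
simulation loop and the filter propagation loop can run inside numba kernels.
Parameter references resolve either to constants (values supplied in
``theta``) or to state indices (parameter pseudo-species of an augmented
network).
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit

from .model import (
    Hill,
    LinearCombination,
    MassAction,
    ModelError,
    ReactionNetwork,
)

KIND_MASS = 0
KIND_HILL = 1
KIND_LC = 2


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array encoding of a network's stoichiometry and kinetics."""

    n: int
    r: int
    reactant: np.ndarray  # (r, n) int64
    net: np.ndarray  # (r, n) int64
    kind: np.ndarray  # (r,) int64
    c_const: np.ndarray  # (r,) mass-action rate constants
    c_idx: np.ndarray  # (r,) state index of the rate, -1 if constant
    hv_c: np.ndarray
    hv_i: np.ndarray
    hk_c: np.ndarray
    hk_i: np.ndarray
    h_n: np.ndarray
    h_mode: np.ndarray  # 0 activator, 1 repressor
    h_reg: np.ndarray
    lc_toff: np.ndarray  # (r+1,) term offsets
    lc_sp: np.ndarray  # per-term species index, -1 for constant term
    lc_c0: np.ndarray  # per-term constant part of the coefficient
    lc_coff: np.ndarray  # (T+1,) coefficient state-index offsets
    lc_cidx: np.ndarray  # flattened state indices added into coefficients

    def kernel_args(self) -> tuple:
        return (
            self.reactant,
            self.net,
            self.kind,
            self.c_const,
            self.c_idx,
            self.hv_c,
            self.hv_i,
            self.hk_c,
            self.hk_i,
            self.h_n,
            self.h_mode,
            self.h_reg,
            self.lc_toff,
            self.lc_sp,
            self.lc_c0,
            self.lc_coff,
            self.lc_cidx,
        )


_COMPILE_CACHE: "weakref.WeakKeyDictionary[ReactionNetwork, dict]" = weakref.WeakKeyDictionary()


def compile_network(
    network: ReactionNetwork, theta: Mapping[str, float] | None = None
) -> CompiledNetwork:
    """Compile a network (with parameter values ``theta`` where needed)."""
    theta = dict(theta or {})
    key = tuple(sorted((k, float(v)) for k, v in theta.items()))
    per_net = _COMPILE_CACHE.setdefault(network, {})
    if key in per_net:
        return per_net[key]

    names = network.names
    idx = {name: i for i, name in enumerate(names)}
    n, r = network.n, network.r

    def resolve(ref):
        """Return (constant, state_index) for a rate reference."""
        if isinstance(ref, str):
            if ref in idx:
                return 0.0, idx[ref]
            if ref in theta:
                return float(theta[ref]), -1
            raise ModelError(f"no value supplied for parameter {ref!r}")
        return float(ref), -1

    reactant = np.zeros((r, n), dtype=np.int64)
    net = np.zeros((r, n), dtype=np.int64)
    kind = np.zeros(r, dtype=np.int64)
    c_const = np.zeros(r)
    c_idx = np.full(r, -1, dtype=np.int64)
    hv_c = np.zeros(r)
    hv_i = np.full(r, -1, dtype=np.int64)
    hk_c = np.zeros(r)
    hk_i = np.full(r, -1, dtype=np.int64)
    h_n = np.zeros(r)
    h_mode = np.zeros(r, dtype=np.int64)
    h_reg = np.zeros(r, dtype=np.int64)
    lc_toff = np.zeros(r + 1, dtype=np.int64)
    lc_sp: list[int] = []
    lc_c0: list[float] = []
    lc_coff: list[int] = [0]
    lc_cidx: list[int] = []

    for j, rxn in enumerate(network.reactions):
        for name, nu in rxn.reactants.items():
            reactant[j, idx[name]] = int(nu)
        net[j] = rxn.net_change(names)
        prop = rxn.propensity
        if isinstance(prop, MassAction):
            kind[j] = KIND_MASS
            c_const[j], c_idx[j] = resolve(prop.rate)
        elif isinstance(prop, Hill):
            kind[j] = KIND_HILL
            hv_c[j], hv_i[j] = resolve(prop.vmax)
            hk_c[j], hk_i[j] = resolve(prop.K)
            h_n[j] = float(prop.n)
            h_mode[j] = 0 if prop.mode == "activator" else 1
            h_reg[j] = idx[prop.regulator]
        elif isinstance(prop, LinearCombination):
            kind[j] = KIND_LC
            for coeffs, sp in prop.terms:
                c0 = 0.0
                for c in coeffs:
                    cc, ci = resolve(c)
                    if ci < 0:
                        c0 += cc
                    else:
                        lc_cidx.append(ci)
                lc_c0.append(c0)
                lc_sp.append(idx[sp] if sp is not None else -1)
                lc_coff.append(len(lc_cidx))
        else:  # pragma: no cover - exhaustive over kinetics kinds
            raise ModelError(f"unknown kinetics {prop!r}")
        lc_toff[j + 1] = len(lc_sp)

    enc = CompiledNetwork(
        n=n,
        r=r,
        reactant=reactant,
        net=net,
        kind=kind,
        c_const=c_const,
        c_idx=c_idx,
        hv_c=hv_c,
        hv_i=hv_i,
        hk_c=hk_c,
        hk_i=hk_i,
        h_n=h_n,
        h_mode=h_mode,
        h_reg=h_reg,
        lc_toff=lc_toff,
        lc_sp=np.asarray(lc_sp, dtype=np.int64),
        lc_c0=np.asarray(lc_c0, dtype=float),
        lc_coff=np.asarray(lc_coff, dtype=np.int64),
        lc_cidx=np.asarray(lc_cidx, dtype=np.int64),
    )
    per_net[key] = enc
    return enc


# ---------------------------------------------------------------------------
# vectorized propensity evaluation (used when building generators)
# ---------------------------------------------------------------------------


def eval_propensities(enc: CompiledNetwork, X: np.ndarray) -> np.ndarray:
    """Propensities for a batch of states ``X`` of shape ``(m, n)``.

    Returns an ``(m, r)`` array; rates are clamped to zero wherever a
    reactant count is below its stoichiometric requirement.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    out = np.zeros((m, enc.r))
    for j in range(enc.r):
        if enc.kind[j] == KIND_MASS:
            lam = np.full(m, enc.c_const[j]) if enc.c_idx[j] < 0 else X[:, enc.c_idx[j]].copy()
            for i in np.nonzero(enc.reactant[j])[0]:
                for k in range(enc.reactant[j, i]):
                    lam = lam * (X[:, i] - k)
        elif enc.kind[j] == KIND_HILL:
            vmax = enc.hv_c[j] if enc.hv_i[j] < 0 else X[:, enc.hv_i[j]]
            K = enc.hk_c[j] if enc.hk_i[j] < 0 else X[:, enc.hk_i[j]]
            u = X[:, enc.h_reg[j]] ** enc.h_n[j]
            Kn = K ** enc.h_n[j]
            lam = vmax * (u / (Kn + u) if enc.h_mode[j] == 0 else Kn / (Kn + u))
        else:
            lam = np.zeros(m)
            for t in range(enc.lc_toff[j], enc.lc_toff[j + 1]):
                c = np.full(m, enc.lc_c0[t])
                for p in range(enc.lc_coff[t], enc.lc_coff[t + 1]):
                    c = c + X[:, enc.lc_cidx[p]]
                mult = 1.0 if enc.lc_sp[t] < 0 else X[:, enc.lc_sp[t]]
                lam = lam + c * mult
        ok = np.ones(m, dtype=bool)
        for i in np.nonzero(enc.reactant[j])[0]:
            ok &= X[:, i] >= enc.reactant[j, i]
        out[:, j] = np.where(ok, lam, 0.0)
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _props_one(
    x,
    reactant,
    net,
    kind,
    c_const,
    c_idx,
    hv_c,
    hv_i,
    hk_c,
    hk_i,
    h_n,
    h_mode,
    h_reg,
    lc_toff,
    lc_sp,
    lc_c0,
    lc_coff,
    lc_cidx,
    out,
):
    r = kind.shape[0]
    n = x.shape[0]
    for j in range(r):
        ok = True
        for i in range(n):
            if reactant[j, i] > 0 and x[i] < reactant[j, i]:
                ok = False
                break
        if not ok:
            out[j] = 0.0
            continue
        if kind[j] == 0:
            lam = c_const[j] if c_idx[j] < 0 else x[c_idx[j]]
            for i in range(n):
                nu = reactant[j, i]
                for k in range(nu):
                    lam *= x[i] - k
        elif kind[j] == 1:
            vmax = hv_c[j] if hv_i[j] < 0 else x[hv_i[j]]
            K = hk_c[j] if hk_i[j] < 0 else x[hk_i[j]]
            u = x[h_reg[j]] ** h_n[j]
            Kn = K ** h_n[j]
            if h_mode[j] == 0:
                lam = vmax * u / (Kn + u)
            else:
                lam = vmax * Kn / (Kn + u)
        else:
            lam = 0.0
            for t in range(lc_toff[j], lc_toff[j + 1]):
                c = lc_c0[t]
                for p in range(lc_coff[t], lc_coff[t + 1]):
                    c += x[lc_cidx[p]]
                if lc_sp[t] < 0:
                    lam += c
                else:
                    lam += c * x[lc_sp[t]]
        out[j] = lam


@njit(cache=True)
def _ssa_kernel(
    x0,
    t0,
    t_end,
    seed,
    max_events,
    reactant,
    net,
    kind,
    c_const,
    c_idx,
    hv_c,
    hv_i,
    hk_c,
    hk_i,
    h_n,
    h_mode,
    h_reg,
    lc_toff,
    lc_sp,
    lc_c0,
    lc_coff,
    lc_cidx,
):
    """Direct-method SSA; returns (times, states, n_events, status).

    status: 0 ok, -1 event buffer overflow, -2 invalid propensity.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    r = kind.shape[0]
    times = np.empty(max_events)
    states = np.empty((max_events, n))
    props = np.empty(r)
    x = x0.copy()
    t = t0
    m = 0
    while True:
        _props_one(
            x, reactant, net, kind, c_const, c_idx, hv_c, hv_i, hk_c, hk_i,
            h_n, h_mode, h_reg, lc_toff, lc_sp, lc_c0, lc_coff, lc_cidx, props,
        )
        total = 0.0
        for j in range(r):
            lam = props[j]
            if lam < 0.0 or not np.isfinite(lam):
                return times, states, m, -2
            total += lam
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            break
        u = np.random.random() * total
        acc = 0.0
        jsel = r - 1
        for j in range(r):
            acc += props[j]
            if u <= acc:
                jsel = j
                break
        if m >= max_events:
            return times, states, m, -1
        for i in range(n):
            x[i] += net[jsel, i]
        times[m] = t
        for i in range(n):
            states[m, i] = x[i]
        m += 1
    return times, states, m, 0


@njit(cache=True)
def _expmv_unif(data, indices, indptr, v, t, alpha, tol):
    """Action of ``exp(A t)`` on ``v`` by uniformization.

    ``A`` (CSR, rows are target states) must have a nonpositive diagonal with
    ``alpha >= max |A_ii|``; the transition kernel ``P = I + A/alpha`` is then
    substochastic and the Poisson-weighted series converges monotonically.
    The interval is substepped so the Poisson rate per step stays moderate.
    """
    n = v.shape[0]
    w = v.copy()
    if t <= 0.0 or alpha <= 0.0:
        return w
    nsub = int(alpha * t / 50.0) + 1
    dt = t / nsub
    at = alpha * dt
    term = np.empty(n)
    new = np.empty(n)
    out = np.empty(n)
    for _ in range(nsub):
        coeff = np.exp(-at)
        acc = coeff
        for i in range(n):
            term[i] = w[i]
            out[i] = coeff * w[i]
        k = 0
        while acc < 1.0 - tol and k < 100000:
            k += 1
            for row in range(n):
                s = 0.0
                for p in range(indptr[row], indptr[row + 1]):
                    s += data[p] * term[indices[p]]
                new[row] = term[row] + s / alpha
            for i in range(n):
                term[i] = new[i]
            coeff *= at / k
            acc += coeff
            for i in range(n):
                out[i] += coeff * term[i]
        for i in range(n):
            w[i] = out[i]
    return w


@njit(cache=True)
def _expmv_unif_inplace(data, indices, indptr, w, t, alpha, tol, term, new, out):
    """In-place variant of :func:`_expmv_unif` with caller-owned scratch
    arrays; returns the (sub-)probability mass of the result."""
    n = w.shape[0]
    if t <= 0.0 or alpha <= 0.0:
        s = 0.0
        for i in range(n):
            s += w[i]
        return s
    nsub = int(alpha * t / 50.0) + 1
    dt = t / nsub
    at = alpha * dt
    for _ in range(nsub):
        coeff = np.exp(-at)
        acc = coeff
        for i in range(n):
            term[i] = w[i]
            out[i] = coeff * w[i]
        k = 0
        while acc < 1.0 - tol and k < 100000:
            k += 1
            for row in range(n):
                s = 0.0
                for p in range(indptr[row], indptr[row + 1]):
                    s += data[p] * term[indices[p]]
                new[row] = term[row] + s / alpha
            for i in range(n):
                term[i] = new[i]
            coeff *= at / k
            acc += coeff
            for i in range(n):
                out[i] += coeff * term[i]
        for i in range(n):
            w[i] = out[i]
    s = 0.0
    for i in range(n):
        s += w[i]
    return s


@njit(cache=True)
def _eig_block_propagate(V, Vinv, lam, bmap, w, t, bs):
    """Propagate a block-diagonal generator via precomputed per-block
    eigendecompositions: ``w_b <- V e^{lam t} V^{-1} w_b`` for each
    contiguous block; returns the total remaining mass.  Tiny negative
    round-off entries are clipped."""
    nb = bmap.shape[0]
    tmp = np.empty(bs)
    total = 0.0
    for b in range(nb):
        u = bmap[b]
        off = b * bs
        for i in range(bs):
            s = 0.0
            for j in range(bs):
                s += Vinv[u, i, j] * w[off + j]
            tmp[i] = s * np.exp(lam[u, i] * t)
        for i in range(bs):
            s = 0.0
            for j in range(bs):
                s += V[u, i, j] * tmp[j]
            if s < 0.0:
                s = 0.0
            w[off + i] = s
            total += s
    return total


@njit(cache=True)
def _csr_matvec(data, indices, indptr, v):
    n = indptr.shape[0] - 1
    out = np.empty(n)
    for row in range(n):
        s = 0.0
        for p in range(indptr[row], indptr[row + 1]):
            s += data[p] * v[indices[p]]
        out[row] = s
    return out


def expm_action(A_csr, v: np.ndarray, t: float, tol: float = 1e-13) -> np.ndarray:
    """Python-facing wrapper around the uniformization kernel."""
    diag = A_csr.diagonal()
    alpha = float(np.max(-diag)) if diag.size else 0.0
    return _expmv_unif(
        A_csr.data, A_csr.indices, A_csr.indptr, np.asarray(v, dtype=float), float(t), alpha, tol
    )
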
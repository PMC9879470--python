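"""GRM-based REML (GREML): variance components, correlations and GEBVs.

The mixed model per trait is y* = Xβ + u + e with cov(u) = Σg ⊗ G and
cov(e) = Σe ⊗ I, fitted by average-information REML with step-halving and a
line-searched gradient fallback.  X defaults to an intercept; because the
phenotypes are pre-adjusted for population, year, cohort, age and the first
two genotype PCs, the drivers pass the population dummies and PCs back in as
``fixed`` covariates so the likelihood does not expect genetic variance along
the breed contrasts that the adjustment removed (the classical
lost-degrees-of-freedom correction for pre-adjusted data).

Two computational paths share the same likelihood:

* balanced (every trait observed on the same animals): the GRM is
  eigendecomposed once (cached on the GRM object) and every REML iteration is
  O(n) in the rotated basis;
* general (arbitrary per-trait missingness, e.g. the across-breed fits where
  the two "traits" live on disjoint animals): dense covariance with one
  Cholesky per iteration.

Missing records are handled by row deletion in the likelihood; GEBVs are
produced for every animal in the GRM, including unphenotyped ones, through
the genomic relationships.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GRM, subset_grm

logger = logging.getLogger(__name__)

__all__ = [
    "GREMLFit",
    "GenomicCorrelationEstimate",
    "fit_greml",
    "run_all_bivariates",
    "genomic_correlation_across_breeds",
]

MIN_RECORDS = 30
VAR_FLOOR_FRAC = 1e-8  # variance floor as a fraction of phenotypic variance
CORR_CAP = 0.999


# ---------------------------------------------------------------------------
# results

@dataclass
class GREMLFit:
    """One (bi)variate REML fit: components, derived parameters, GEBVs."""

    traits: tuple[str, ...]
    animal_ids: np.ndarray
    Vg: np.ndarray
    Ve: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    gebv: pd.DataFrame | None
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def h2(self) -> np.ndarray:
        vg, ve = np.diag(self.Vg), np.diag(self.Ve)
        return vg / (vg + ve)

    @property
    def rg(self) -> float | None:
        if len(self.traits) < 2:
            return None
        den = np.sqrt(self.Vg[0, 0] * self.Vg[1, 1])
        return float(self.Vg[0, 1] / den) if den > 0 else np.nan

    @property
    def re(self) -> float | None:
        if len(self.traits) < 2:
            return None
        den = np.sqrt(self.Ve[0, 0] * self.Ve[1, 1])
        return float(self.Ve[0, 1] / den) if den > 0 else np.nan


@dataclass
class GenomicCorrelationEstimate:
    """Across-breed genomic correlation of one trait in a breed pair."""

    trait: str
    breed_pair: tuple[str, str]
    rg_across: float
    vg: dict[str, float]
    converged: bool
    fit: GREMLFit


# ---------------------------------------------------------------------------
# parameterisation helpers

def _param_list(t: int, resid_cov_zero: bool):
    """Ordered parameter descriptors (kind, row, col)."""
    params = [("g", a, a) for a in range(t)]
    params += [("g", a, b) for a, b in itertools.combinations(range(t), 2)]
    params += [("e", a, a) for a in range(t)]
    if not resid_cov_zero:
        params += [("e", a, b) for a, b in itertools.combinations(range(t), 2)]
    return params


def _unpack(theta: np.ndarray, params, t: int):
    vg = np.zeros((t, t))
    ve = np.zeros((t, t))
    for val, (kind, a, b) in zip(theta, params):
        m = vg if kind == "g" else ve
        m[a, b] = m[b, a] = val
    return vg, ve


def _pack(vg: np.ndarray, ve: np.ndarray, params) -> np.ndarray:
    out = []
    for kind, a, b in params:
        out.append((vg if kind == "g" else ve)[a, b])
    return np.array(out)


def _fix_bounds(theta: np.ndarray, params, t: int, vary: np.ndarray) -> np.ndarray:
    """Clamp variances to the floor and cap covariances at |r| = 0.999."""
    vg, ve = _unpack(theta, params, t)
    for m in (vg, ve):
        for a in range(t):
            m[a, a] = max(m[a, a], VAR_FLOOR_FRAC * vary[a])
        for a, b in itertools.combinations(range(t), 2):
            cap = CORR_CAP * np.sqrt(m[a, a] * m[b, b])
            m[a, b] = m[b, a] = np.clip(m[a, b], -cap, cap)
    return _pack(vg, ve, params)


# ---------------------------------------------------------------------------
# balanced path: GRM eigenbasis, O(n) iterations

class _BalancedModel:
    """All traits observed on the same animals; q fixed covariates per trait.

    Works in the GRM eigenbasis: for eigenpair (dᵢ, uᵢ) the rotated record
    ỹᵢ ~ N(βᵀcᵢ, Wᵢ) with Wᵢ = dᵢΣg + Σe, independent across i, where cᵢ is
    the rotated covariate row.  Everything is O(n·q²·t²) per iteration.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, grm_sub: GRM, params,
                 t: int):
        vals, vecs = grm_sub.eigendecomposition()
        self.d = np.clip(vals, 0.0, None)
        self.U = vecs
        self.Yt = vecs.T @ y
        self.C = vecs.T @ x
        self.n, self.t = y.shape
        self.q = x.shape[1]
        self.params = params

    def loglik(self, theta: np.ndarray):
        vg, ve = _unpack(theta, self.params, self.t)
        t, q = self.t, self.q
        w = self.d[:, None, None] * vg + ve
        sign, logdet = np.linalg.slogdet(w)
        if np.any(sign <= 0):
            return None
        winv = np.linalg.inv(w)
        m = np.einsum("ia,ib,isu->asbu", self.C, self.C, winv,
                      optimize=True).reshape(q * t, q * t)
        msign, mlogdet = np.linalg.slogdet(m)
        if msign <= 0:
            return None
        rhs = np.einsum("ia,isu,iu->as", self.C, winv, self.Yt,
                        optimize=True).reshape(q * t)
        beta = np.linalg.solve(m, rhs).reshape(q, t)
        r = self.Yt - self.C @ beta
        py = np.einsum("isu,iu->is", winv, r)
        quad = float(np.sum(r * py))
        ll = -0.5 * (float(logdet.sum()) + float(mlogdet) + quad
                     + (self.n * t - q * t) * np.log(2 * np.pi))
        aux = {"winv": winv, "minv": np.linalg.inv(m), "py": py,
               "beta": beta}
        return ll, aux

    def score_ai(self, theta: np.ndarray, aux):
        winv, minv, py = aux["winv"], aux["minv"], aux["py"]
        p = len(self.params)
        t, q = self.t, self.q
        score = np.zeros(p)
        qs = []
        for k, (kind, a, b) in enumerate(self.params):
            phi = np.zeros((t, t))
            phi[a, b] = phi[b, a] = 1.0
            w_k = self.d if kind == "g" else np.ones(self.n)
            tr1 = float(np.sum(w_k * np.einsum("ijk,jk->i", winv, phi)))
            wpw = np.einsum("isu,uv,ivw->isw", winv, phi, winv,
                            optimize=True)
            n_k = np.einsum("ia,ib,i,isw->asbw", self.C, self.C, w_k, wpw,
                            optimize=True).reshape(q * t, q * t)
            tr2 = float(np.trace(minv @ n_k))
            qv = w_k[:, None] * (py @ phi)
            ypvpy = float(np.sum(py * qv))
            score[k] = -0.5 * (tr1 - tr2 - ypvpy)
            qs.append(qv)
        ai = np.zeros((p, p))
        pq = []
        for qv in qs:
            wq = np.einsum("isu,iu->is", winv, qv)
            gam_rhs = np.einsum("ia,is->as", self.C, wq).reshape(q * t)
            gam = (minv @ gam_rhs).reshape(q, t)
            xg = self.C @ gam
            pq.append(wq - np.einsum("isu,iu->is", winv, xg))
        for k in range(p):
            for l in range(k, p):
                ai[k, l] = ai[l, k] = 0.5 * float(np.sum(qs[k] * pq[l]))
        return score, ai

    def gebv(self, theta: np.ndarray, aux) -> np.ndarray:
        vg, _ = _unpack(theta, self.params, self.t)
        ut = self.d[:, None] * (aux["py"] @ vg)
        return self.U @ ut

    def vinv_resid(self, aux) -> np.ndarray:
        """V⁻¹(y − Xβ̂) per trait column, in the original animal basis."""
        return self.U @ aux["py"]


# ---------------------------------------------------------------------------
# dense path: arbitrary missing patterns

class _DenseModel:
    """Stacked observed records with dense V = Σg⊗G + Σe⊗I on them."""

    def __init__(self, y: np.ndarray, x: np.ndarray, grm_sub: GRM, params,
                 t: int):
        self.G = grm_sub.values
        self.n_animals = grm_sub.n
        self.params = params
        self.t = t
        self.obs = [np.flatnonzero(~np.isnan(y[:, j])) for j in range(t)]
        self.yv = np.concatenate([y[self.obs[j], j] for j in range(t)])
        self.N = self.yv.size
        offs = np.cumsum([0] + [o.size for o in self.obs])
        self.seg = [(offs[j], offs[j + 1]) for j in range(t)]
        q = x.shape[1]
        xd = np.zeros((self.N, q * t))
        for j, (lo, hi) in enumerate(self.seg):
            xd[lo:hi, j * q:(j + 1) * q] = x[self.obs[j]]
        # drop all-zero columns (covariates vanishing on a trait's records)
        keep = np.abs(xd).sum(axis=0) > 0
        self.X = _prune_columns(xd[:, keep], warn=False)
        self.p_fixed = int(self.X.shape[1])
        # V is linear in theta: precompute the constant derivative matrices
        self.dV = []
        for kind, a, b in params:
            m = np.zeros((self.N, self.N))
            blocks = [(a, b)] if a == b else [(a, b), (b, a)]
            for r, cidx in blocks:
                lo_r, hi_r = self.seg[r]
                lo_c, hi_c = self.seg[cidx]
                if kind == "g":
                    m[lo_r:hi_r, lo_c:hi_c] = self.G[np.ix_(self.obs[r],
                                                            self.obs[cidx])]
                else:
                    ids_r, ids_c = self.obs[r], self.obs[cidx]
                    common, ir, ic = np.intersect1d(ids_r, ids_c,
                                                    return_indices=True)
                    m[lo_r + ir, lo_c + ic] = 1.0
            self.dV.append(m)

    def loglik(self, theta: np.ndarray):
        v = np.zeros((self.N, self.N))
        for val, m in zip(theta, self.dV):
            v += val * m
        try:
            cf = cho_factor(v, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vinv_x = cho_solve(cf, self.X, check_finite=False)
        s = self.X.T @ vinv_x
        ssign, slogdet = np.linalg.slogdet(s)
        if ssign <= 0:
            return None
        beta = np.linalg.solve(s, vinv_x.T @ self.yv)
        resid = self.yv - self.X @ beta
        py = cho_solve(cf, resid, check_finite=False)
        quad = float(resid @ py)
        ll = -0.5 * (logdet + float(slogdet) + quad
                     + (self.N - self.p_fixed) * np.log(2 * np.pi))
        aux = {"cf": cf, "vinv_x": vinv_x, "sinv": np.linalg.inv(s),
               "py": py, "beta": beta}
        return ll, aux

    def score_ai(self, theta: np.ndarray, aux):
        cf, vinv_x, sinv, py = (aux["cf"], aux["vinv_x"], aux["sinv"],
                                aux["py"])
        vinv = cho_solve(cf, np.eye(self.N), check_finite=False)
        pmat = vinv - vinv_x @ sinv @ vinv_x.T
        p = len(self.params)
        score = np.zeros(p)
        q = np.empty((self.N, p))
        for k, m in enumerate(self.dV):
            trace = float(np.sum(pmat * m))
            q[:, k] = m @ py
            score[k] = -0.5 * (trace - float(py @ q[:, k]))
        pq = pmat @ q
        ai = 0.5 * (q.T @ pq)
        return score, ai

    def gebv(self, theta: np.ndarray, aux) -> np.ndarray:
        vg, _ = _unpack(theta, self.params, self.t)
        py = aux["py"]
        u = np.zeros((self.n_animals, self.t))
        for j, (lo, hi) in enumerate(self.seg):
            contrib = self.G[:, self.obs[j]] @ py[lo:hi]
            for s in range(self.t):
                u[:, s] += vg[s, j] * contrib
        return u


# ---------------------------------------------------------------------------
# the AI-REML driver

def _ai_reml(model, theta0, params, t, vary, tol, max_iter):
    theta = _fix_bounds(theta0, params, t, vary)
    res = model.loglik(theta)
    if res is None:
        theta = _fix_bounds(_pack(np.diag(vary) * 0.5, np.diag(vary) * 0.5,
                                  params), params, t, vary)
        res = model.loglik(theta)
        if res is None:
            raise RuntimeError("REML likelihood undefined at starting values")
    ll, aux = res
    path = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, ai = model.score_ai(theta, aux)
        directions = []
        try:
            ridge = 1e-8 * max(np.abs(np.diag(ai)).max(), 1.0)
            directions.append(np.linalg.solve(ai + ridge * np.eye(len(score)),
                                              score))
        except np.linalg.LinAlgError:
            pass
        # gradient fallback, scaled to a comparable magnitude
        gnorm = np.linalg.norm(score)
        if gnorm > 0:
            directions.append(score / gnorm * max(np.abs(theta).max(), 1e-6))
        accepted = False
        ll_new = ll
        for delta in directions:
            step = 1.0
            for _ in range(30):
                cand = _fix_bounds(theta + step * delta, params, t, vary)
                res = model.loglik(cand)
                if res is not None and res[0] > ll:
                    theta, (ll_new, aux) = cand, res
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            converged = True
            break
        path.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return theta, ll, aux, converged, n_iter, path


# ---------------------------------------------------------------------------
# public API

def _canonical_sorted(grm: GRM) -> GRM:
    """GRM with animals sorted by id (cached), so results are exactly
    invariant to the input animal order."""
    order = np.argsort(grm.animal_ids.astype(str), kind="stable")
    if np.array_equal(order, np.arange(grm.n)):
        return grm
    cache = grm.__dict__.get("_canonical_cache")
    if cache is None:
        cache = subset_grm(grm, grm.animal_ids[order])
        grm.__dict__["_canonical_cache"] = cache
    return cache


def _subset_cached(grm: GRM, mask: np.ndarray) -> GRM:
    """Cached principal submatrix for a boolean observation mask."""
    key = mask.tobytes()
    cache = grm.__dict__.setdefault("_subset_cache", {})
    if key not in cache:
        cache[key] = subset_grm(grm, grm.animal_ids[mask])
    return cache[key]


def _prune_columns(x: np.ndarray, warn: bool = True) -> np.ndarray:
    """Keep a maximal independent subset of design columns (intercept first)."""
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return x
    keep = [0]
    for j in range(1, x.shape[1]):
        if np.linalg.matrix_rank(x[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    if warn:
        warnings.warn(
            f"dropping {x.shape[1] - len(keep)} aliased fixed-effect columns")
    return x[:, keep]


def _fixed_design(fixed: pd.DataFrame | None, ids: np.ndarray) -> np.ndarray:
    """Intercept plus the user covariates, aligned to the GRM animals;
    aliased columns are dropped with a warning."""
    n = len(ids)
    x = np.ones((n, 1))
    if fixed is not None:
        if "animal_id" in fixed.columns:
            fixed = fixed.set_index("animal_id")
        block = fixed.reindex(ids).to_numpy(dtype=float)
        if np.isnan(block).any():
            raise KeyError("fixed covariates missing for some GRM animals")
        x = _prune_columns(np.hstack([x, block]))
    return x


def fit_greml(
    y_star: pd.DataFrame,
    grm: GRM,
    fixed: pd.DataFrame | None = None,
    resid_cov_zero: bool = False,
    max_iter: int = 200,
    tol: float = 1e-8,
    compute_gebv: bool = True,
    min_records: int = MIN_RECORDS,
) -> GREMLFit:
    """REML fit of one or two traits against a GRM.

    Parameters
    ----------
    y_star
        Adjusted phenotypes indexed by animal_id (NaN = missing).  Every
        animal must be present in the GRM; GRM animals absent from the index
        are treated as unphenotyped and still receive GEBVs.
    grm
        Genomic relationship matrix covering the analysis set.
    fixed
        Optional fixed-effect covariates per animal (applied to each trait);
        an intercept is always included.  Pass the covariates used during
        pre-adjustment so the likelihood does not attribute the removed
        contrasts to the genetic variance.
    resid_cov_zero
        Fix the residual covariance between the two traits at zero (used by
        the across-breed fits where no animal records both traits).
    """
    if "animal_id" in getattr(y_star, "columns", []):
        y_star = y_star.set_index("animal_id")
    traits = tuple(y_star.columns)
    t = len(traits)
    if t not in (1, 2):
        raise ValueError("fit_greml handles one or two traits")
    grm = _canonical_sorted(grm)
    unknown = set(y_star.index) - set(grm.animal_ids)
    if unknown:
        raise KeyError(f"animals not in GRM: {sorted(unknown)[:5]}")
    y = y_star.reindex(grm.animal_ids).to_numpy(dtype=float)
    x_full = _fixed_design(fixed, grm.animal_ids)

    n_obs_any = int(np.sum(~np.isnan(y).all(axis=1)))
    if n_obs_any < min_records:
        raise ValueError(
            f"{n_obs_any} records observed (minimum {min_records})")

    vary = np.array([np.nanvar(y[:, j], ddof=1) for j in range(t)])
    if np.any(~np.isfinite(vary)) or np.any(vary <= 0):
        raise ValueError("a trait has zero or undefined phenotypic variance")

    params = _param_list(t, resid_cov_zero)
    vg0 = 0.5 * np.diag(vary)
    ve0 = 0.5 * np.diag(vary)
    if t == 2 and not resid_cov_zero:
        both = ~np.isnan(y).any(axis=1)
        if both.sum() > 3:
            c = np.cov(y[both].T)[0, 1]
            vg0[0, 1] = vg0[1, 0] = 0.5 * c
            ve0[0, 1] = ve0[1, 0] = 0.5 * c
    theta0 = _pack(vg0, ve0, params)

    any_missing = bool(np.isnan(y).any())
    row_missing = np.isnan(y).all(axis=1)
    balanced = (not any_missing) and not resid_cov_zero
    same_pattern = (t == 1) or (not resid_cov_zero and not np.isnan(
        y[~row_missing]).any())

    if balanced:
        model = _BalancedModel(y, x_full, grm, params, t)
        sub_ids = grm.animal_ids
    elif same_pattern:
        # identical per-trait pattern: solve on the observed block, then
        # propagate predictions to every animal through G
        mask = ~row_missing
        sub = _subset_cached(grm, mask)
        x_sub = _prune_columns(x_full[mask], warn=False)
        model = _BalancedModel(y[mask], x_sub, sub, params, t)
        sub_ids = sub.animal_ids
    else:
        model = _DenseModel(y, x_full, grm, params, t)
        sub_ids = grm.animal_ids

    theta, ll, aux, converged, n_iter, path = _ai_reml(
        model, theta0, params, t, vary, tol, max_iter)
    vg, ve = _unpack(theta, params, t)

    gebv = None
    if compute_gebv:
        u = model.gebv(theta, aux)
        if balanced or isinstance(model, _DenseModel):
            gebv = pd.DataFrame(u, index=pd.Index(grm.animal_ids,
                                                  name="animal_id"),
                                columns=list(traits))
        else:
            # extend predictions from the observed block to all animals
            mask = ~row_missing
            vy = model.vinv_resid(aux)  # V_obs^{-1}(y_obs - X beta)
            cross = grm.values[:, np.flatnonzero(mask)]
            u_all = np.zeros((grm.n, t))
            for j in range(t):
                for s in range(t):
                    u_all[:, s] += vg[s, j] * (cross @ vy[:, j])
            gebv = pd.DataFrame(u_all, index=pd.Index(grm.animal_ids,
                                                      name="animal_id"),
                                columns=list(traits))

    if not converged:
        logger.warning("REML did not converge in %d iterations for %s",
                       max_iter, traits)
    return GREMLFit(
        traits=traits, animal_ids=np.asarray(sub_ids, dtype=object),
        Vg=vg, Ve=ve, loglik=ll, converged=converged, n_iter=n_iter,
        gebv=gebv, loglik_path=path)


def run_all_bivariates(
    adj,
    grm: GRM,
    traits: list[str] | None = None,
    fixed: pd.DataFrame | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[dict[tuple[str, str], GREMLFit], pd.DataFrame, pd.DataFrame]:
    """All pairwise bivariate fits plus the summary matrix.

    Returns ``(fits, summary, gebv_w)`` where ``summary`` is the trait ×
    trait matrix with the per-trait mean heritability (over the fits
    containing that trait) on the diagonal, genetic correlations above and
    residual correlations below, and ``gebv_w`` the per-trait whole-data GEBV
    averaged over the fits containing the trait.
    """
    values = adj.values if not isinstance(adj, pd.DataFrame) else adj
    if traits is None:
        traits = list(values.columns)
    fits: dict[tuple[str, str], GREMLFit] = {}
    failures: dict[tuple[str, str], Exception] = {}
    for a, b in itertools.combinations(traits, 2):
        try:
            fits[(a, b)] = fit_greml(values[[a, b]], grm, fixed=fixed,
                                     max_iter=max_iter, tol=tol)
        except Exception as exc:  # noqa: BLE001 - recorded, summary proceeds
            failures[(a, b)] = exc
    if failures:
        logger.warning("%d bivariate fits failed: %s", len(failures),
                       sorted(failures))

    t = len(traits)
    summary = pd.DataFrame(np.full((t, t), np.nan), index=traits,
                           columns=traits)
    h2_samples: dict[str, list[float]] = {tr: [] for tr in traits}
    gebv_sum = pd.DataFrame(0.0, index=pd.Index(grm.animal_ids,
                                                name="animal_id"),
                            columns=traits)
    gebv_cnt = pd.Series(0, index=traits, dtype=int)
    for (a, b), fit in fits.items():
        h2 = fit.h2
        h2_samples[a].append(float(h2[0]))
        h2_samples[b].append(float(h2[1]))
        summary.loc[a, b] = fit.rg
        summary.loc[b, a] = fit.re
        if fit.gebv is not None:
            gebv_sum[a] += fit.gebv[a].reindex(gebv_sum.index).to_numpy()
            gebv_sum[b] += fit.gebv[b].reindex(gebv_sum.index).to_numpy()
            gebv_cnt[a] += 1
            gebv_cnt[b] += 1
    for tr in traits:
        if h2_samples[tr]:
            summary.loc[tr, tr] = float(np.mean(h2_samples[tr]))
    gebv_w = gebv_sum.div(gebv_cnt.replace(0, np.nan), axis=1)
    return fits, summary, gebv_w


def genomic_correlation_across_breeds(
    trait: str,
    breed_a: str,
    breed_b: str,
    adj,
    grm: GRM,
    breed_labels: pd.Series,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GenomicCorrelationEstimate:
    """Across-breed genomic correlation: the trait in breed A and in breed B
    are modelled as two traits on the breed-pair GRM with residual covariance
    fixed at zero (no animal records both)."""
    values = adj.values if not isinstance(adj, pd.DataFrame) else adj
    breed_labels = pd.Series(breed_labels)
    ids_a = breed_labels.index[breed_labels == breed_a]
    ids_b = breed_labels.index[breed_labels == breed_b]
    y = values[trait]
    n_a = int(y.reindex(ids_a).notna().sum())
    n_b = int(y.reindex(ids_b).notna().sum())
    if min(n_a, n_b) < MIN_RECORDS:
        raise ValueError(
            f"{trait}: breeds {breed_a}/{breed_b} have {n_a}/{n_b} records "
            f"(minimum {MIN_RECORDS} each)")
    pair_ids = list(ids_a) + list(ids_b)
    sub = subset_grm(grm, pair_ids)
    frame = pd.DataFrame(np.nan, index=pd.Index(pair_ids, name="animal_id"),
                         columns=[f"{trait}@{breed_a}", f"{trait}@{breed_b}"])
    frame.loc[ids_a, f"{trait}@{breed_a}"] = y.reindex(ids_a).to_numpy()
    frame.loc[ids_b, f"{trait}@{breed_b}"] = y.reindex(ids_b).to_numpy()
    fit = fit_greml(frame, sub, resid_cov_zero=True, max_iter=max_iter,
                    tol=tol, compute_gebv=False)
    return GenomicCorrelationEstimate(
        trait=trait, breed_pair=(breed_a, breed_b),
        rg_across=float(np.clip(fit.rg, -1.0, 1.0)),
        vg={breed_a: float(fit.Vg[0, 0]), breed_b: float(fit.Vg[1, 1])},
        converged=fit.converged, fit=fit)
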
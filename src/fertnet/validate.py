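"""Cross-validation schemes and GEBV quality metrics.

Two validation schemes mirror the study design:

* scheme 1 (leave-one-breed-out): each breed in turn has all its phenotypes
  set missing in the reference, one fold per breed;
* scheme 2 (within-breed 5-fold): animals are partitioned, stratified within
  breed, into five disjoint 20% folds.

Whole-data GEBVs (û_w) and partial-data GEBVs (û_p, validation records
masked) are compared with the LR method: accuracy
ACC_LR = √( cov(û_w, û_p) / ((1 + F̄ − 2f̄)·σ²_g) ), bias
Bias_LR = mean(û_p) − mean(û_w) and dispersion
Disp_LR = 1 − cov(û_w, û_p)/var(û_p), where F̄ is the mean inbreeding
(mean diagonal of G minus 1) and 2f̄ the mean off-diagonal relationship among
validation animals, and σ²_g is the additive variance estimated from the
partial data.  The square root in ACC_LR follows the LR-method definition of
accuracy; the ratio itself estimates the squared accuracy.  The traditional
correlation-based accuracy is ACC_R = cor(û_p, y*)/√h².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .greml import fit_greml
from .grm import GRM, subset_grm

logger = logging.getLogger(__name__)

__all__ = [
    "make_folds",
    "acc_r",
    "method_lr",
    "LRMetrics",
    "run_validation",
    "summarize_validation",
    "anova_metrics",
]


def make_folds(
    pheno: pd.DataFrame,
    scheme: int,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build (reference_ids, validation_ids) folds for a scheme.

    Scheme 1 yields one fold per breed with that breed entirely in
    validation; scheme 2 yields ``k`` folds whose validation sets partition
    every breed (stratified within breed, seeded).
    """
    ids = pheno["animal_id"].to_numpy(dtype=object)
    breeds = pheno["breed"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated animal ids")
    uniq = list(dict.fromkeys(breeds))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == 1:
        if len(uniq) < 2:
            raise ValueError("scheme 1 (leave-one-breed-out) needs >= 2 breeds")
        for b in uniq:
            val = ids[breeds == b]
            ref = ids[breeds != b]
            folds.append((ref, val))
        return folds
    if scheme == 2:
        rng = np.random.default_rng(seed)
        assignment = np.empty(len(ids), dtype=int)
        for b in uniq:
            rows = np.flatnonzero(breeds == b)
            if rows.size < k:
                warnings.warn(
                    f"breed {b}: {rows.size} animals for {k} folds; "
                    "some folds will miss this breed")
            perm = rng.permutation(rows)
            assignment[perm] = np.arange(perm.size) % k
        for f in range(k):
            val = ids[assignment == f]
            ref = ids[assignment != f]
            folds.append((ref, val))
        return folds
    raise ValueError(f"unknown scheme {scheme}; expected 1 or 2")


def acc_r(u_p: np.ndarray, y_star: np.ndarray, h2: float) -> float:
    """Correlation-based accuracy cor(û_p, y*)/√h² on validation records.

    Returns NaN (flagged via a warning) when either vector has zero
    variance.  Values above 1 are possible and expected for this estimator.
    """
    if h2 <= 0:
        raise ValueError("acc_r requires h2 > 0")
    u_p = np.asarray(u_p, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    if u_p.size != y_star.size or u_p.size < 3:
        raise ValueError("need >= 3 aligned validation records")
    if np.std(u_p) == 0 or np.std(y_star) == 0:
        warnings.warn("acc_r undefined: zero-variance input")
        return float("nan")
    return float(np.corrcoef(u_p, y_star)[0, 1] / np.sqrt(h2))


@dataclass
class LRMetrics:
    acc_lr: float
    bias_lr: float
    disp_lr: float
    F_bar: float
    f2_bar: float
    cov_wp: float


def method_lr(
    u_w: np.ndarray,
    u_p: np.ndarray,
    g_block: np.ndarray,
    sigma2_g: float,
) -> LRMetrics:
    """LR-method accuracy, bias and dispersion on aligned validation animals.

    ``g_block`` is the validation × validation block of the GRM; ``sigma2_g``
    the additive variance from the partial fit.  A negative covariance leaves
    the accuracy undefined (NaN), not zero.
    """
    u_w = np.asarray(u_w, dtype=float)
    u_p = np.asarray(u_p, dtype=float)
    if u_w.shape != u_p.shape or u_w.ndim != 1:
        raise ValueError("u_w and u_p must be aligned 1-d vectors")
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    n = u_w.size
    if g_block.shape != (n, n):
        raise ValueError("g_block must match the validation animals")
    f_bar = float(np.mean(np.diag(g_block)) - 1.0)
    if n > 1:
        off = g_block[~np.eye(n, dtype=bool)]
        f2_bar = float(off.mean())
        cov_wp = float(np.cov(u_w, u_p, ddof=1)[0, 1])
        var_p = float(np.var(u_p, ddof=1))
        var_w = float(np.var(u_w, ddof=1))
    else:
        f2_bar, cov_wp, var_p, var_w = 0.0, np.nan, 0.0, 0.0
    denom = (1.0 + f_bar - f2_bar) * sigma2_g
    if cov_wp >= 0 and denom > 0:
        acc = float(np.sqrt(cov_wp / denom))
    else:
        acc = float("nan")
    bias = float(np.mean(u_p) - np.mean(u_w))
    # var(u_p) numerically zero (e.g. a partial fit at the variance floor)
    # leaves the regression slope, hence the dispersion, undefined
    if var_p > 1e-12 * max(var_w, 1.0):
        disp = 1.0 - cov_wp / var_p
    else:
        disp = float("nan")
    return LRMetrics(acc_lr=acc, bias_lr=bias, disp_lr=float(disp),
                     F_bar=f_bar, f2_bar=f2_bar, cov_wp=cov_wp)


def run_validation(
    adj,
    grm: GRM,
    breed_labels: pd.Series,
    scheme: int,
    k: int = 5,
    seed: int = 0,
    traits: list[str] | None = None,
    fixed: pd.DataFrame | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Run one validation scheme over every trait and breed.

    Whole-data and partial-data univariate GREML fits are compared per
    (breed, trait, fold); returns one row per combination with ACC_R, the LR
    metrics, the relationship summaries of the validation block, the
    partial-fit σ²_g and h², and the validation count.
    """
    values = adj.values if not isinstance(adj, pd.DataFrame) else adj
    if traits is None:
        traits = list(values.columns)
    breed_labels = pd.Series(breed_labels)
    pheno = pd.DataFrame({
        "animal_id": values.index.to_numpy(dtype=object),
        "breed": breed_labels.reindex(values.index).to_numpy(dtype=object),
    })
    folds = make_folds(pheno, scheme, k=k, seed=seed)

    whole: dict[str, object] = {}
    for trait in traits:
        whole[trait] = fit_greml(values[[trait]], grm, fixed=fixed,
                                 max_iter=max_iter, tol=tol)

    rows = []
    for f, (_, val_ids) in enumerate(folds):
        val_set = set(val_ids)
        for trait in traits:
            y = values[trait].copy()
            mask_val = y.index.isin(val_set)
            y_masked = y.copy()
            y_masked[mask_val] = np.nan
            if y_masked.notna().sum() < 30:
                logger.warning("fold %d trait %s: too few reference records",
                               f, trait)
                continue
            partial = fit_greml(y_masked.to_frame(), grm, fixed=fixed,
                                max_iter=max_iter, tol=tol)
            sigma2_g = float(partial.Vg[0, 0])
            h2_partial = float(partial.h2[0])
            h2_whole = float(whole[trait].h2[0])
            u_w_all = whole[trait].gebv[trait]
            u_p_all = partial.gebv[trait]
            fold_breeds = ([pheno.loc[pheno["animal_id"].isin(val_set),
                                      "breed"].iloc[0]]
                           if scheme == 1 else
                           list(dict.fromkeys(breed_labels)))
            for breed in fold_breeds:
                b_ids = [a for a in val_ids
                         if breed_labels.get(a) == breed
                         and not np.isnan(y.get(a, np.nan))]
                if len(b_ids) < 3:
                    continue
                u_w = u_w_all.reindex(b_ids).to_numpy()
                u_p = u_p_all.reindex(b_ids).to_numpy()
                g_block = subset_grm(grm, b_ids).values
                lr = method_lr(u_w, u_p, g_block, max(sigma2_g, 1e-12))
                if h2_partial < 1e-4:
                    # no genetic variance estimated from the partial data:
                    # the LR accuracy and dispersion are undefined
                    lr.acc_lr = float("nan")
                    lr.disp_lr = float("nan")
                rows.append({
                    "scheme": scheme, "breed": breed, "trait": trait,
                    "fold": f,
                    "acc_r": acc_r(u_p, y.reindex(b_ids).to_numpy(),
                                   max(h2_whole, 1e-6)),
                    "acc_lr": lr.acc_lr, "bias_lr": lr.bias_lr,
                    "disp_lr": lr.disp_lr, "F_bar": lr.F_bar,
                    "f2_bar": lr.f2_bar, "sigma2_g": sigma2_g,
                    "h2_partial": h2_partial, "h2_whole": h2_whole,
                    "n_validation": len(b_ids),
                })
    return pd.DataFrame(rows)


def summarize_validation(results: pd.DataFrame) -> pd.DataFrame:
    """Per-trait means of the four metrics (folds and breeds averaged),
    the layout of the study's accuracy/bias/dispersion table."""
    cols = ["acc_r", "acc_lr", "bias_lr", "disp_lr"]
    return results.groupby("trait", sort=False)[cols].mean()


def anova_metrics(
    results: pd.DataFrame,
    metrics: tuple[str, ...] = ("acc_r", "acc_lr", "bias_lr", "disp_lr"),
) -> dict[str, dict]:
    """Linear-model decomposition of each metric.

    Fits metric ~ h² (partial-fit estimate, covariate) + breed + trait
    (+ fold when several folds are present) and returns per metric the model
    R² and per-factor F-test p-values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    out: dict[str, dict] = {}
    df = results.copy()
    use_fold = df["fold"].nunique() > 1
    for metric in metrics:
        sub = df[np.isfinite(df[metric])]
        if sub.empty or sub[metric].nunique() == 1:
            warnings.warn(f"{metric}: constant or empty; ANOVA undefined")
            out[metric] = {"r2": 0.0, "p_values": {}}
            continue
        terms = ["h2_partial", "C(breed)", "C(trait)"]
        terms = [t for t in terms
                 if t.startswith("h2") or
                 sub[t[2:-1]].nunique() > 1]
        if use_fold and sub["fold"].nunique() > 1:
            terms.append("C(fold)")
        formula = f"{metric} ~ " + " + ".join(terms)
        model = smf.ols(formula, data=sub).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                table = sm.stats.anova_lm(model, typ=2)
                pvals = {idx: float(p) for idx, p in
                         table["PR(>F)"].items() if idx != "Residual"}
            except Exception:  # noqa: BLE001 - aliased design
                warnings.warn(f"{metric}: aliased factors; p-values dropped")
                pvals = {}
        out[metric] = {"r2": float(model.rsquared), "p_values": pvals}
    return out
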
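"""Traditional (between-animal) QTL mapping on feature counts.

Peak phenotypes: raw ChIP and input counts are normalized by the per-animal
mean across peaks, log-transformed, and the per-peak OLS residual of
ln(PN+1) on ln(IN+1) becomes the phenotype, removing input-depth artefacts.
Exon phenotypes: counts below a median of 5 are dropped, the rest are
variance-stabilized with a median-of-ratios size-factor log2 transform and
batch mean-centred.  Outlier animals are removed by a single-pass 4-SD rule
on the first seven principal components.  Association uses a linear mixed
model with a leave-one-chromosome-out genomic relationship matrix, variance
components estimated by REML through one spectral decomposition per
phenotype (EMMA-style), and per-SNP generalized-least-squares Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats, optimize

from asqtl.datatypes import PhasedGenotypePanel


# ---------------------------------------------------------------- peak QC

def qc_peaks(peak_counts: pd.DataFrame, input_counts: pd.DataFrame,
             quantile: float = 0.01, input_fold: float = 5.0,
             ) -> Tuple[pd.Index, pd.DataFrame]:
    """Remove peaks with total ChIP count below the 1% quantile and peaks
    whose total input count exceeds ``input_fold`` times the mean.

    The quantile is the empirical quantile with linear interpolation,
    applied to per-peak totals across animals.  Returns the retained peak
    index and a removal log.
    """
    if not peak_counts.index.equals(input_counts.index):
        raise ValueError("peak and input matrices must share their peak index")
    totals = peak_counts.sum(axis=1)
    in_totals = input_counts.sum(axis=1)
    thr = float(np.quantile(totals.to_numpy(), quantile))
    low = totals < thr
    artefact = in_totals > input_fold * in_totals.mean()
    log_rows = [(pid, "below-quantile") for pid in totals.index[low]]
    log_rows += [(pid, "input-artefact") for pid in totals.index[artefact & ~low]]
    keep = totals.index[~(low | artefact)]
    if len(keep) == 0:
        raise RuntimeError("peak QC removed every peak")
    return keep, pd.DataFrame(log_rows, columns=["feature_id", "reason"])


def normalize_peak_phenotype(peak_counts: pd.DataFrame, input_counts: pd.DataFrame,
                             ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak residual phenotype after removing input-depth effects.

    Counts are divided by the per-animal mean across peaks (PN, IN), then
    per peak i the model ln(PN_i+1) = alpha + beta ln(IN_i+1) + eps is fit
    by OLS and the residual vector eps is the phenotype.

    Returns (phenotypes, coefficients); phenotypes is peaks x animals,
    coefficients has columns alpha, beta.
    """
    pk = peak_counts.to_numpy(dtype=float)
    inp = input_counts.to_numpy(dtype=float)
    pmean = pk.mean(axis=0)
    imean = inp.mean(axis=0)
    ok = (pmean > 0) & (imean > 0)
    if not ok.all():
        dropped = list(np.asarray(peak_counts.columns)[~ok])
        warnings.warn(f"animals with zero mean count dropped: {dropped}")
    cols = np.asarray(peak_counts.columns)[ok]
    y = np.log(pk[:, ok] / pmean[ok] + 1.0)
    x = np.log(inp[:, ok] / imean[ok] + 1.0)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc ** 2).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    alpha = y.mean(axis=1) - beta * x.mean(axis=1)
    resid = y - alpha[:, None] - beta[:, None] * x
    pheno = pd.DataFrame(resid, index=peak_counts.index, columns=cols)
    coef = pd.DataFrame({"alpha": alpha, "beta": beta}, index=peak_counts.index)
    return pheno, coef


# ---------------------------------------------------------- expression VST

def transform_expression(exon_counts: pd.DataFrame,
                         batches: Optional[pd.Series] = None,
                         min_median: float = 5.0) -> pd.DataFrame:
    """Variance-stabilized, batch-adjusted exon expression phenotypes.

    Exons with median count < ``min_median`` are excluded.  The transform is
    log2(count / size_factor + 1) with median-of-ratios size factors, then
    per-batch mean-centring (grand mean preserved) removes the sequencing
    batch effect.  Batches with a single animal are left uncentred.
    """
    med = exon_counts.median(axis=1)
    kept = exon_counts.loc[med >= min_median]
    if kept.empty:
        raise RuntimeError("no exons pass the median filter")
    mat = kept.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if finite.any():
        ref = np.exp(logs[finite].mean(axis=1))
        ratios = mat[finite] / ref[:, None]
        size = np.median(ratios, axis=0)
    else:
        size = mat.mean(axis=0)
        size = size / size.mean()
    size = np.where(size > 0, size, 1.0)
    vst = np.log2(mat / size[None, :] + 1.0)
    out = pd.DataFrame(vst, index=kept.index, columns=kept.columns)

    if batches is not None:
        grand = out.mean(axis=1)
        adj = out.copy()
        for b, members in batches.groupby(batches).groups.items():
            cols = [c for c in members if c in out.columns]
            if len(cols) < 2:
                warnings.warn(f"batch {b!r} has fewer than 2 animals; not centred")
                continue
            bmean = out[cols].mean(axis=1)
            adj[cols] = out[cols].sub(bmean, axis=0).add(grand, axis=0)
        out = adj
    return out


# ------------------------------------------------------------ PCA outliers

def pca_outlier_filter(phenotypes: pd.DataFrame, n_components: int = 7,
                       sd_limit: float = 4.0) -> Tuple[List, pd.DataFrame]:
    """Single-pass removal of animals beyond ``sd_limit`` SDs on any of the
    first ``n_components`` principal components of the phenotype matrix
    (features x animals).  Returns (retained animal ids, score table)."""
    animals = list(phenotypes.columns)
    x = phenotypes.to_numpy(dtype=float).T  # animals x features
    n = x.shape[0]
    k = min(n_components, n - 1, x.shape[1])
    if k < n_components:
        warnings.warn(f"only {k} components available; capping")
    if k < 1:
        return animals, pd.DataFrame(index=animals)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    sd = scores.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    zs = np.abs((scores - scores.mean(axis=0)) / sd)
    outlier = (zs > sd_limit).any(axis=1)
    retained = [a for a, o in zip(animals, outlier) if not o]
    table = pd.DataFrame(scores, index=animals,
                         columns=[f"PC{i + 1}" for i in range(k)])
    table["outlier"] = outlier
    return retained, table


# -------------------------------------------------------------------- GRM

@dataclass
class Grm:
    """VanRaden genomic relationship matrix with leave-one-chromosome-out
    variants, stored as per-chromosome cross-product blocks."""

    animals: List[str]
    blocks: Dict[str, np.ndarray] = field(default_factory=dict)
    m_used: Dict[str, int] = field(default_factory=dict)

    def full(self) -> np.ndarray:
        m = sum(self.m_used.values())
        return sum(self.blocks.values()) / m

    def loco(self, chrom: str) -> np.ndarray:
        m = sum(v for c, v in self.m_used.items() if c != chrom)
        if m == 0:
            raise ValueError(f"no SNPs outside {chrom}")
        s = sum(v for c, v in self.blocks.items() if c != chrom)
        return s / m


def build_grm(panel: PhasedGenotypePanel, min_snps: int = 1) -> Grm:
    """First VanRaden GRM: G = W W' / m with columns of W standardized as
    (x - 2p) / sqrt(2 p (1-p)); monomorphic SNPs are skipped.  LOCO
    variants reuse per-chromosome blocks, so loco(c) equals the GRM built
    from the complement SNP set exactly."""
    x = panel.dosage().astype(float)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    grm = Grm(animals=list(panel.animals))
    chroms = panel.snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = (chroms == chrom) & poly
        m = int(sel.sum())
        if m < min_snps:
            continue
        w = (x[:, sel] - 2 * p[sel]) / np.sqrt(2 * p[sel] * (1 - p[sel]))
        grm.blocks[chrom] = w @ w.T
        grm.m_used[chrom] = m
    if not grm.m_used:
        raise ValueError("no polymorphic SNPs for the GRM")
    return grm


# -------------------------------------------------------------------- MLM

@dataclass
class MixedModel:
    """REML fit of y = X c + u + e with cov(u) = sigma_g^2 K, solved in the
    eigenbasis of K so that per-SNP tests are weighted least squares."""

    eigvecs: np.ndarray
    eigvals: np.ndarray
    y_rot: np.ndarray
    x_rot: np.ndarray
    delta: float  # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float


def _reml_neg_loglik(log_delta, s, y_rot, x_rot):
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    xtwy = x_rot.T @ (w * y_rot)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    r = y_rot - x_rot @ beta
    rss = float((w * r * r).sum())
    n, p = x_rot.shape
    df = n - p
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or rss <= 0:
        return np.inf
    ll = -0.5 * (df * np.log(2 * np.pi * rss / df) + df
                 + np.sum(np.log(s + delta)) + logdet_xtwx)
    return -ll


def eigen_kinship(kinship: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (possibly near-singular) GRM; reusable across
    every phenotype fit with the same LOCO matrix."""
    k = np.asarray(kinship, dtype=float)
    s, u = np.linalg.eigh(k)
    if s.min() < -1e-8:
        k = k + 1e-6 * np.eye(k.shape[0])
        s, u = np.linalg.eigh(k)
    return np.clip(s, 0.0, None), u


def fit_mixed_model(y: np.ndarray, covariates: np.ndarray,
                    kinship: Optional[np.ndarray] = None,
                    eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                    ) -> MixedModel:
    """Estimate variance components by REML on the eigen-rotated model."""
    if eig is None:
        eig = eigen_kinship(kinship)
    s, u = eig
    y_rot = u.T @ np.asarray(y, dtype=float)
    x_rot = u.T @ np.asarray(covariates, dtype=float)
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=(-12.0, 12.0),
                                   args=(s, y_rot, x_rot), method="bounded")
    delta = float(np.exp(res.x))
    w = 1.0 / (s + delta)
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    beta = np.linalg.solve(xtwx, x_rot.T @ (w * y_rot))
    r = y_rot - x_rot @ beta
    n, p = x_rot.shape
    sigma_g2 = float((w * r * r).sum() / (n - p))
    return MixedModel(eigvecs=u, eigvals=s, y_rot=y_rot, x_rot=x_rot,
                      delta=delta, sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2)


def mlm_association(y: pd.Series, dosages: pd.DataFrame,
                    kinship: Optional[np.ndarray] = None,
                    covariates: Optional[pd.DataFrame] = None,
                    eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                    ) -> pd.DataFrame:
    """Mixed-linear-model association of one phenotype against candidate SNPs.

    Parameters
    ----------
    y : phenotype indexed by animal.
    dosages : animals x SNPs alternate-allele dosage matrix (0/1/2),
        typically restricted to the ±1 Mb cis window of the feature.
    kinship : GRM over the same animals, normally the LOCO variant for the
        feature's chromosome.
    covariates : optional animal-indexed covariates (e.g. sequencing
        batch); a categorical column is one-hot encoded with a reference
        level, and an intercept is always included.

    Variance components are estimated once under the covariate-only model;
    each SNP is then tested by generalized least squares with a Wald p.
    """
    animals = list(y.index)
    xc = _design(covariates, animals)
    model = fit_mixed_model(y.to_numpy(dtype=float), xc, kinship, eig=eig)
    w = 1.0 / (model.eigvals + model.delta)
    g_rot = model.eigvecs.T @ dosages.loc[animals].to_numpy(dtype=float)
    n = len(animals)
    rows = []
    for j, snp in enumerate(dosages.columns):
        xf = np.column_stack([model.x_rot, g_rot[:, j]])
        xtwx = xf.T @ (w[:, None] * xf)
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            continue
        beta = xtwx_inv @ (xf.T @ (w * model.y_rot))
        r = model.y_rot - xf @ beta
        dof = n - xf.shape[1]
        if dof <= 0:
            continue
        s2 = float((w * r * r).sum() / dof)
        se = float(np.sqrt(max(s2 * xtwx_inv[-1, -1], 0.0)))
        if se == 0:
            continue
        t = beta[-1] / se
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append({"snp_id": snp, "beta": float(beta[-1]), "se": se,
                     "p": float(p), "n_used": n})
    return pd.DataFrame(rows, columns=["snp_id", "beta", "se", "p", "n_used"])


def _design(covariates: Optional[pd.DataFrame], animals: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(animals))]
    if covariates is not None:
        cov = covariates.loc[list(animals)]
        for name in cov.columns:
            col = cov[name]
            if col.dtype.kind in "OUSb" or str(col.dtype) == "category" or col.nunique() < 20 and col.dtype.kind in "iu":
                dummies = pd.get_dummies(col, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def scan_feature_qtl(features, kind: str, phenotypes: pd.DataFrame,
                     panel: PhasedGenotypePanel, grm: Grm,
                     covariates: Optional[pd.DataFrame] = None,
                     window: int = 1_000_000) -> pd.DataFrame:
    """Cis-window MLM association for every feature of a kind.

    Returns one row per (feature, SNP) with beta, se, p; the LOCO GRM of
    the feature's chromosome is used for each fit.
    """
    pos = panel.snps["pos"].to_numpy()
    chroms = panel.snps["chrom"].to_numpy()
    dosage = pd.DataFrame(panel.dosage(), index=panel.animals,
                          columns=panel.snps["snp_id"])
    feats = features.of_kind(kind)
    animals = [a for a in phenotypes.columns]
    pos_of = dict(zip(panel.snps["snp_id"], panel.snps["pos"]))
    eig_cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    out = []
    for row in feats.itertuples():
        if row.feature_id not in phenotypes.index:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        sel = (chroms == row.chrom) & (np.abs(pos - mid) <= window)
        snp_ids = panel.snps["snp_id"].to_numpy()[sel]
        if len(snp_ids) == 0:
            continue
        if row.chrom not in eig_cache:
            try:
                k = grm.loco(row.chrom)
            except ValueError:
                k = grm.full()
            ai = [grm.animals.index(a) for a in animals]
            eig_cache[row.chrom] = eigen_kinship(k[np.ix_(ai, ai)])
        y = phenotypes.loc[row.feature_id, animals]
        res = mlm_association(y, dosage.loc[animals, snp_ids],
                              covariates=covariates, eig=eig_cache[row.chrom])
        res.insert(0, "feature_id", row.feature_id)
        res["pos"] = [int(pos_of[s]) for s in res["snp_id"]]
        res["distance_bp"] = res["pos"] - mid
        out.append(res)
    if not out:
        return pd.DataFrame(columns=["feature_id", "snp_id", "beta", "se",
                                     "p", "n_used", "pos", "distance_bp"])
    return pd.concat(out, ignore_index=True)
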
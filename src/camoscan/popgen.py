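"""Population structure and differentiation over the panel.

PCA runs on true genotypes (the synthetic pipeline knows them exactly, so
no genotype-likelihood layer is needed): sites are standardized by their
allele-frequency mean and binomial standard deviation and the individual x
individual covariance is eigendecomposed. Differentiation uses the
Weir & Cockerham (1984) variance-components FST estimator, per site,
globally (sum a / sum(a+b+c)) or in non-overlapping stepping windows
(default 1 kb; 150 bp available). The depth/differentiation coupling test
pairs per-window absolute depth differences between two populations with
the window FST estimates under a Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import DepthTrack
from .intervals import GenomicInterval
from .synth import PopulationGenotypes


# ----------------------------------------------------------------- WC FST

def _wc_components(genotypes: np.ndarray, labels: list[str]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham per-site variance components a, b, c (biallelic)."""
    labels = np.asarray(labels)
    pops = np.unique(labels)
    r = pops.size
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([(labels == p).sum() for p in pops], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("need at least two individuals per population")
    # per-pop allele frequency and heterozygote frequency per site
    p_i = np.stack([
        genotypes[labels == p].mean(axis=0) / 2.0 for p in pops
    ])  # (r, sites)
    h_i = np.stack([
        (genotypes[labels == p] == 1).mean(axis=0) for p in pops
    ])
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
        / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def wc_fst(genotypes: np.ndarray, labels: list[str]) -> float:
    """Multi-site (global) Weir–Cockerham estimate: sum a / sum(a+b+c)."""
    a, b, c = _wc_components(genotypes, labels)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def wc_fst_per_site(genotypes: np.ndarray, labels: list[str]) -> np.ndarray:
    """Per-site estimates (NaN where the site is uninformative)."""
    a, b, c = _wc_components(genotypes, labels)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, a / denom, np.nan)


def pairwise_fst(pg: PopulationGenotypes) -> pd.DataFrame:
    """Global pairwise estimates between every pair of populations."""
    labels = np.asarray(pg.labels)
    pops = pg.populations()
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            sel = (labels == pa) | (labels == pb)
            rows.append(
                dict(pop_a=pa, pop_b=pb,
                     fst=wc_fst(pg.genotypes[sel], labels[sel].tolist()))
            )
    return pd.DataFrame(rows)


def fst_windows(
    genotypes: np.ndarray, labels: list[str], site_pos: np.ndarray,
    regions: list[GenomicInterval], window_size: int = 1000,
    contig: str | None = None,
) -> pd.DataFrame:
    """Stepping-window estimates: sum a / sum(a+b+c) over sites per window.

    Windows tile each region without overlap; windows with no sites carry
    no estimate (NaN) rather than zero.
    """
    a, b, c = _wc_components(genotypes, labels)
    denom = a + b + c
    rows = []
    for region in regions:
        for ws in range(region.start, region.end, window_size):
            we = min(ws + window_size, region.end)
            sel = (site_pos >= ws) & (site_pos < we)
            n = int(sel.sum())
            if n and denom[sel].sum() != 0:
                est = float(a[sel].sum() / denom[sel].sum())
            else:
                est = float("nan")
            rows.append(
                dict(contig=contig or region.contig, start=ws, end=we,
                     fst=est, n_sites=n)
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    coords: np.ndarray            # (individuals, components)
    explained: np.ndarray         # explained-variance fractions, decreasing
    labels: list[str]

    def silhouette_pc1(self) -> float:
        """Mean silhouette of the population labels along PC1."""
        pc1 = self.coords[:, 0]
        labels = np.asarray(self.labels)
        pops = np.unique(labels)
        scores = []
        for i in range(pc1.size):
            d = np.abs(pc1 - pc1[i])
            own = labels == labels[i]
            a = d[own & (np.arange(pc1.size) != i)].mean()
            b = min(d[labels == p].mean() for p in pops if p != labels[i])
            scores.append((b - a) / max(a, b))
        return float(np.mean(scores))


def genotype_pca(genotypes: np.ndarray, labels: list[str],
                 n_components: int = 10) -> PcaResult:
    """PCA of standardized genotypes via the sample covariance eigenbasis.

    Sites with zero minor-allele frequency are dropped; each remaining site
    is centred at 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)).
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] < 2:
        raise ValueError("need at least two individuals")
    p_hat = g.mean(axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    if not np.any(keep):
        raise ValueError("all sites are monomorphic")
    g = g[:, keep]
    p_hat = p_hat[keep]
    x = (g - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0)
    eigvec = eigvec[:, order]
    m = min(n_components, eigval.size)
    total = eigval.sum()
    explained = eigval[:m] / total if total > 0 else np.zeros(m)
    # deterministic sign: largest-magnitude loading positive
    coords = eigvec[:, :m].copy()
    for j in range(m):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return PcaResult(coords, explained, list(labels))


def pc1_label_permutation_p(result: PcaResult, n_perm: int = 999,
                            seed: int = 0) -> float:
    """Permutation p-value for label separation along PC1.

    Statistic: between-group variance of PC1 population means. Under
    exchangeable labels (no structure) the observed statistic is typical.
    """
    rng = np.random.default_rng(seed)
    pc1 = result.coords[:, 0]
    labels = np.asarray(result.labels)

    def stat(lab):
        return np.var([pc1[lab == p].mean() for p in np.unique(lab)])

    obs = stat(labels)
    hits = sum(
        stat(rng.permutation(labels)) >= obs for _ in range(n_perm)
    )
    return (hits + 1) / (n_perm + 1)


# ----------------------------------------------- depth vs differentiation

def depth_fst_correlation(
    windows: pd.DataFrame, depth_a: DepthTrack, depth_b: DepthTrack,
) -> tuple[float, float, bool]:
    """Spearman correlation of |depth difference| vs window FST.

    Returns (rho, p, degenerate). Degenerate (all-tied) input reports
    rho = 0 with the flag set rather than NaN.
    """
    diffs, fsts = [], []
    for row in windows.itertuples():
        if not np.isfinite(row.fst):
            continue
        iv = GenomicInterval(row.contig, row.start, row.end)
        da = float(depth_a.region_values(iv).mean())
        db = float(depth_b.region_values(iv).mean())
        diffs.append(abs(da - db))
        fsts.append(row.fst)
    if len(diffs) < 3:
        raise ValueError("fewer than 3 complete windows")
    diffs = np.asarray(diffs)
    fsts = np.asarray(fsts)
    if np.all(diffs == diffs[0]) or np.all(fsts == fsts[0]):
        return 0.0, 1.0, True
    rho, p = stats.spearmanr(diffs, fsts)
    return float(rho), float(p), False
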
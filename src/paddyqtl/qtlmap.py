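"""QTL mapping engine for selfed RIL populations.

Implements the classical interval-mapping tool chain: genotype probabilities
from a two-state hidden Markov model on a 1 cM pseudomarker grid (Kosambi map
function), Haley–Knott (HK) regression scans, genome-wide permutation
thresholds, two-locus scans, stepwise multi-QTL model selection, and 1.5-LOD
support intervals.

Model notes
-----------
* RILs by selfing are treated as two-state (AA/BB): residual heterozygotes
  (~1.6% at F7) are set to missing rather than modelled as a third state.
* Map distances are meiotic (Kosambi) cM.  Between grid positions d cM apart
  the meiotic recombination fraction is the inverse Kosambi transform
  r = 0.5·tanh(2d/100); the chance that two RIL loci carry different parental
  alleles is the Haldane–Waddington fixation probability R = 2r/(1+2r),
  which is what the HMM uses for its transitions.
* LOD = (n/2)·log10(RSS0/RSS1); numerically perfect fits are capped at 300.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paddyqtl.core import CODE_A, CODE_B, CODE_MISSING, GeneticMap, GenotypeMatrix, rng_for

LOD_CAP = 300.0


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi(r):
    """Kosambi map distance d (cM) for recombination fraction r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def inverse_kosambi(d_cM):
    """Recombination fraction for a Kosambi distance d (cM >= 0)."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * np.tanh(2 * d / 100.0)


def haldane(r):
    """Haldane map distance d (cM) for recombination fraction r."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log(1 - 2 * r)


def inverse_haldane(d_cM):
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1 - np.exp(-2 * d / 100.0))


def ril_self_R(r):
    """RIL-level allele-difference probability 2r/(1+2r) (selfing, F-infinity)."""
    r = np.asarray(r, dtype=float)
    return 2 * r / (1 + 2 * r)


def ril_self_r(R):
    """Invert 2r/(1+2r): meiotic r from an observed RIL mismatch fraction."""
    R = np.asarray(R, dtype=float)
    return R / (2.0 * (1.0 - R))


def ril_self_R_finite(r: float, generation: int = 7) -> float:
    """Exact two-locus mismatch probability among doubly-fixed F_t lines.

    Iterates the diplotype distribution of a selfed lineage started from the
    F1 (AB/ab) with meiotic recombination fraction ``r``.  Returns
    P(recombinant | both loci homozygous) at generation ``generation``; for
    generation -> infinity this converges to the Haldane-Waddington value
    2r/(1+2r), but at F7 it is a few percent smaller, which matters when
    estimating map length.
    """
    # haplotypes 0=AB 1=Ab 2=aB 3=ab; state = unordered diplotype pair
    def gametes(h1, h2):
        if h1 == h2:
            return {h1: 1.0}
        a1, b1 = divmod(h1, 2)
        a2, b2 = divmod(h2, 2)
        out: dict[int, float] = {}
        for h, p in ((h1, (1 - r) / 2), (h2, (1 - r) / 2),
                     (2 * a1 + b2, r / 2), (2 * a2 + b1, r / 2)):
            out[h] = out.get(h, 0.0) + p
        return out

    states = [(i, j) for i in range(4) for j in range(i, 4)]
    dist = {s: 0.0 for s in states}
    dist[(0, 3)] = 1.0
    for _ in range(generation - 1):
        new = {s: 0.0 for s in states}
        for (h1, h2), p in dist.items():
            if p == 0.0:
                continue
            g = gametes(h1, h2)
            for ga, pa in g.items():
                for gb, pb in g.items():
                    key = (ga, gb) if ga <= gb else (gb, ga)
                    new[key] += p * pa * pb
        dist = new
    fixed = sum(dist[(h, h)] for h in range(4))
    recomb = dist[(1, 1)] + dist[(2, 2)]
    return recomb / fixed if fixed > 0 else 0.0


def ril_self_r_finite(R, generation: int = 7):
    """Invert :func:`ril_self_R_finite` by interpolation on a fine r grid."""
    r_grid = np.linspace(0.0, 0.4999, 400)
    R_grid = np.array([ril_self_R_finite(float(r), generation) for r in r_grid])
    return np.interp(np.asarray(R, dtype=float), R_grid, r_grid)


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

@dataclass
class ProbGrid:
    """Posterior P(BB) per line on a pseudomarker grid, per chromosome.

    ``positions[c]`` is the grid (cM) for chromosome ``chrom_names[c]`` and
    ``p_bb[c]`` the matching (n_lines, n_positions) posterior; P(AA) is its
    complement.  ``is_marker[c]`` flags grid points that coincide with typed
    markers.
    """

    line_ids: list[str]
    chrom_names: list[str]
    positions: list[np.ndarray]
    p_bb: list[np.ndarray]
    is_marker: list[np.ndarray]
    step: float = 1.0
    error_rate: float = 0.01

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def dosage_matrix(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Expected additive dosage E[x] = P(BB) - P(AA) at every grid point.

        Returns the (n_lines, n_positions) matrix and a meta frame with
        columns chrom, pos_cM.
        """
        X = np.concatenate([2.0 * p - 1.0 for p in self.p_bb], axis=1)
        meta = pd.DataFrame(
            {
                "chrom": np.concatenate(
                    [[c] * len(p) for c, p in zip(self.chrom_names, self.positions)]
                ),
                "pos_cM": np.concatenate(self.positions),
            }
        )
        return X, meta

    def index_of(self, chrom: str, pos_cM: float) -> int:
        """Flat grid index of the point nearest (chrom, pos_cM)."""
        offset = 0
        for c, p in zip(self.chrom_names, self.positions):
            if c == chrom:
                return offset + int(np.argmin(np.abs(p - pos_cM)))
            offset += len(p)
        raise KeyError(f"no chromosome named {chrom!r}")


def _emission(codes: np.ndarray, error_rate: float) -> np.ndarray:
    """Per line x marker emission likelihoods for states (AA, BB).

    H and missing calls are uninformative (likelihood 1 in both states).
    """
    n, m = codes.shape
    e = np.ones((n, m, 2))
    a = codes == CODE_A
    b = codes == CODE_B
    e[a, 0] = 1 - error_rate
    e[a, 1] = error_rate
    e[b, 0] = error_rate
    e[b, 1] = 1 - error_rate
    return e


def _forward_backward(e: np.ndarray, R: np.ndarray):
    """Scaled forward-backward for the symmetric 2-state chain.

    e: (n_lines, n_pos, 2) emissions; R: (n_pos-1,) switch probabilities.
    Returns alpha, beta (normalised per step) with posterior ∝ alpha*beta.
    """
    n, m, _ = e.shape
    alpha = np.empty_like(e)
    beta = np.empty_like(e)
    a = 0.5 * e[:, 0, :]
    a /= a.sum(axis=1, keepdims=True)
    alpha[:, 0, :] = a
    for t in range(1, m):
        r = R[t - 1]
        pred = np.empty_like(a)
        pred[:, 0] = a[:, 0] * (1 - r) + a[:, 1] * r
        pred[:, 1] = a[:, 0] * r + a[:, 1] * (1 - r)
        a = pred * e[:, t, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, t, :] = a
    b = np.full((n, 2), 0.5)
    beta[:, m - 1, :] = b
    for t in range(m - 2, -1, -1):
        r = R[t]
        w = e[:, t + 1, :] * b
        nxt = np.empty_like(b)
        nxt[:, 0] = w[:, 0] * (1 - r) + w[:, 1] * r
        nxt[:, 1] = w[:, 0] * r + w[:, 1] * (1 - r)
        b = nxt / nxt.sum(axis=1, keepdims=True)
        beta[:, t, :] = b
    return alpha, beta


def _chrom_grid(positions: np.ndarray, step: float) -> np.ndarray:
    """Pseudomarker grid: every `step` cM from 0 plus all marker positions."""
    length = positions[-1] if len(positions) else 0.0
    grid = np.arange(0.0, length + 1e-9, step)
    grid = np.union1d(np.round(grid, 9), np.round(positions, 9))
    return grid


def genotype_probabilities(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    step: float = 1.0,
    error_rate: float = 0.01,
) -> ProbGrid:
    """Two-state HMM posteriors at 1 cM pseudomarker intervals.

    Transitions use the inverse Kosambi map function at the meiotic level and
    the Haldane–Waddington RIL correction (see module docstring); emissions
    allow a symmetric genotyping error rate.
    """
    if error_rate < 0 or error_rate >= 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    chrom_names, grids, pbbs, marker_flags = [], [], [], []
    for chrom in gmap.chromosomes:
        try:
            midx = [genotypes.marker_index(m) for m in chrom.markers]
        except ValueError as exc:
            raise KeyError(f"mapped marker absent from genotype matrix: {exc}") from exc
        grid = _chrom_grid(chrom.positions, step)
        is_marker = np.isin(grid, np.round(chrom.positions, 9))
        codes_grid = np.full((genotypes.n_lines, len(grid)), CODE_MISSING, dtype=np.int8)
        marker_slots = np.searchsorted(grid, np.round(chrom.positions, 9))
        codes_grid[:, marker_slots] = genotypes.codes[:, midx]
        e = _emission(codes_grid, error_rate)
        r = inverse_kosambi(np.diff(grid))
        R = ril_self_R(r)
        alpha, beta = _forward_backward(e, R) if len(grid) > 1 else (
            e / e.sum(axis=2, keepdims=True),
            np.full_like(e, 0.5),
        )
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        chrom_names.append(chrom.name)
        grids.append(grid)
        pbbs.append(post[:, :, 1])
        marker_flags.append(is_marker)
    return ProbGrid(
        list(genotypes.line_ids), chrom_names, grids, pbbs, marker_flags, step, error_rate
    )


def leave_one_out_posteriors(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    error_rate: float = 0.01,
):
    """Posterior state probabilities at each typed marker, excluding that
    marker's own call (one forward-backward pass per chromosome).

    Returns a dict chrom -> (marker_ids, (n_lines, n_markers, 2) posteriors).
    Used by the genotyping-error LOD filter.
    """
    if error_rate <= 0:
        raise ValueError("error_rate must be positive (error LOD undefined at 0)")
    out = {}
    for chrom in gmap.chromosomes:
        midx = [genotypes.marker_index(m) for m in chrom.markers]
        codes = genotypes.codes[:, midx]
        e = _emission(codes, error_rate)
        if len(chrom.positions) > 1:
            r = inverse_kosambi(np.diff(chrom.positions))
            R = ril_self_R(r)
            alpha, beta = _forward_backward(e, R)
        else:
            alpha = e / e.sum(axis=2, keepdims=True)
            beta = np.full_like(e, 0.5)
        # alpha includes the local emission multiplicatively; dividing it out
        # gives the forward pass with an uninformative call at that marker.
        post = (alpha / e) * beta
        post /= post.sum(axis=2, keepdims=True)
        out[chrom.name] = (list(chrom.markers), post)
    return out


# ---------------------------------------------------------------------------
# Haley-Knott regression scans
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray | None):
    """Project out intercept + covariates; return (Q, residual maker)."""
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(C)
    return Q


def _scan_core(X: np.ndarray, y: np.ndarray, Q: np.ndarray):
    """Per-column simple regression of y on X after removing span(Q).

    Returns (lod, beta, rss1, rss0) for each column of X.
    """
    n = len(y)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    rss0 = float(yr @ yr)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = np.maximum(rss0 - beta * sxy, 0.0)
    if rss0 <= 0:
        return np.zeros(X.shape[1]), beta, rss1, rss0
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * np.log10(np.where(rss1 > 0, rss0 / np.where(rss1 > 0, rss1, 1.0), np.inf))
    lod = np.minimum(np.where(np.isfinite(lod), lod, LOD_CAP), LOD_CAP)
    return lod, beta, rss1, rss0


def _align_phenotype(phenotype, probgrid: ProbGrid):
    """Return (y, keep-mask over grid lines) for an array or Series."""
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probgrid.line_ids).to_numpy(float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != probgrid.n_lines:
            raise ValueError("phenotype length does not match lines in grid")
    keep = np.isfinite(y)
    return y, keep


def hk_scan(phenotype, probgrid: ProbGrid, covariates=None) -> pd.DataFrame:
    """Single-QTL Haley–Knott scan.

    At each grid position the phenotype is regressed on the expected dosage
    E[x] = P(BB) − P(AA) (plus optional covariates); LOD compares against the
    covariate-only null.

    Returns a frame with columns chrom, pos_cM, lod, effect, rss.
    """
    y, keep = _align_phenotype(phenotype, probgrid)
    if keep.sum() < 10:
        raise ValueError("need at least 10 lines with phenotype")
    X, meta = probgrid.dosage_matrix()
    X = X[keep]
    y = y[keep]
    C = None if covariates is None else np.asarray(covariates, float)[keep]
    if np.var(y) == 0:
        warnings.warn("phenotype has zero variance; LOD set to 0 everywhere")
        out = meta.copy()
        out["lod"] = 0.0
        out["effect"] = 0.0
        out["rss"] = 0.0
        return out
    Q = _residualize(y, C)
    lod, beta, rss1, _ = _scan_core(X, y, Q)
    out = meta.copy()
    out["lod"] = lod
    out["effect"] = beta
    out["rss"] = rss1
    return out


def permutation_threshold(
    phenotype,
    probgrid: ProbGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    covariates=None,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Line labels are shuffled against genotypes; the threshold is the
    empirical (1-alpha) quantile (type-7) of the per-permutation maximum
    genome-wide LOD.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y, keep = _align_phenotype(phenotype, probgrid)
    X, _ = probgrid.dosage_matrix()
    X = X[keep]
    y = y[keep]
    n = len(y)
    rng = rng_for(seed, "perm")
    C = None if covariates is None else np.asarray(covariates, float)[keep]
    Q = _residualize(y, C)
    Xr = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    good = sxx > 0
    maxima = np.empty(n_perm)
    # permutations in blocks: LODs for all positions via one matmul per block
    block = max(1, min(n_perm, int(5e7 // max(X.shape[1] * n, 1)) or 1))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        P = np.empty((n, k))
        for j in range(k):
            P[:, j] = y[rng.permutation(n)]
        Pr = P - Q @ (Q.T @ P)
        rss0 = np.einsum("ij,ij->j", Pr, Pr)
        sxy = Xr.T @ Pr  # (m, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = rss0[None, :] - (sxy[good] ** 2) / sxx[good, None]
        rss1 = np.maximum(rss1, 0.0)
        with np.errstate(divide="ignore"):
            lod = (n / 2.0) * np.log10(rss0[None, :] / np.where(rss1 > 0, rss1, np.nan))
        lod = np.where(np.isfinite(lod), lod, LOD_CAP)
        maxima[done : done + k] = np.minimum(lod, LOD_CAP).max(axis=0)
        done += k
    return float(np.quantile(maxima, 1 - alpha, method="linear"))


def lod_interval(scan: pd.DataFrame, chrom: str, drop: float = 1.5) -> tuple[float, float]:
    """1.5-LOD support interval around a chromosome's peak.

    The widest contiguous run around the peak with LOD >= peak - drop,
    expanded by one flanking grid point each side and truncated at the
    chromosome ends.
    """
    sub = scan[scan["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"chromosome {chrom!r} not in scan")
    lod = sub["lod"].to_numpy()
    pos = sub["pos_cM"].to_numpy()
    peak = int(np.argmax(lod))
    thresh = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thresh:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    return float(pos[lo]), float(pos[hi])


# ---------------------------------------------------------------------------
# two-locus scans
# ---------------------------------------------------------------------------

def _fit_lod(y: np.ndarray, design: np.ndarray, rss0: float) -> tuple[float, np.ndarray, float]:
    """LOD of y ~ design (with intercept) vs the intercept-only null."""
    n = len(y)
    A = np.column_stack([np.ones(n), design])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(resid @ resid)
    if rss <= 0 or rss0 <= 0:
        return LOD_CAP if rss0 > 0 else 0.0, coef, rss
    return min((n / 2.0) * np.log10(rss0 / rss), LOD_CAP), coef, rss


def scan_two(phenotype, probgrid: ProbGrid, coarse_step: float = 5.0) -> pd.DataFrame:
    """Two-locus scan on a coarse grid.

    For every grid pair (p < q) fit the full model (both dosages plus their
    product) and the additive model; report LODs vs the null and the
    interaction LOD (full - additive).
    """
    y, keep = _align_phenotype(phenotype, probgrid)
    X, meta = probgrid.dosage_matrix()
    X = X[keep]
    y = y[keep]
    sel = _coarse_indices(meta, coarse_step)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    rows = []
    for a_i in range(len(sel)):
        i = sel[a_i]
        xi = X[:, i]
        for b_i in range(a_i + 1, len(sel)):
            j = sel[b_i]
            xj = X[:, j]
            lod_add, _, _ = _fit_lod(y, np.column_stack([xi, xj]), rss0)
            lod_full, _, _ = _fit_lod(y, np.column_stack([xi, xj, xi * xj]), rss0)
            rows.append(
                (
                    meta["chrom"].iat[i],
                    meta["pos_cM"].iat[i],
                    meta["chrom"].iat[j],
                    meta["pos_cM"].iat[j],
                    lod_full,
                    lod_add,
                    max(lod_full - lod_add, 0.0),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom1", "pos1_cM", "chrom2", "pos2_cM", "lod_full", "lod_add", "lod_int"],
    )


def _coarse_indices(meta: pd.DataFrame, coarse_step: float) -> np.ndarray:
    sel = []
    for chrom, grp in meta.groupby("chrom", sort=False):
        pos = grp["pos_cM"].to_numpy()
        want = np.arange(pos[0], pos[-1] + 1e-9, coarse_step)
        idx = grp.index.to_numpy()
        for w in want:
            sel.append(idx[int(np.argmin(np.abs(pos - w)))])
    return np.unique(np.asarray(sel))


def scan_two_penalties(
    phenotype,
    probgrid: ProbGrid,
    n_perm: int = 100,
    alpha: float = 0.05,
    coarse_step: float = 5.0,
    seed: int = 0,
) -> dict:
    """Permutation penalties for stepwise search.

    ``main`` is the (1-alpha) quantile of the genome-wide single-scan maximum;
    ``interaction`` the same quantile of the maximum interaction LOD from the
    two-locus scan.
    """
    y, keep = _align_phenotype(phenotype, probgrid)
    ys = pd.Series(np.asarray(phenotype, float) if not isinstance(phenotype, pd.Series) else phenotype.to_numpy(float), index=probgrid.line_ids)
    main = permutation_threshold(ys, probgrid, max(n_perm, 100), alpha, seed)
    rng = rng_for(seed, "scan2perm")
    y0, keep = _align_phenotype(ys, probgrid)
    yv = y0[keep]
    maxima = []
    for _ in range(min(n_perm, 50)):  # interaction maxima are costly; small B
        perm = pd.Series(rng.permutation(yv), index=np.asarray(probgrid.line_ids)[keep])
        st = scan_two(perm, probgrid, coarse_step)
        maxima.append(st["lod_int"].max())
    return {
        "main": float(main),
        "interaction": float(np.quantile(maxima, 1 - alpha, method="linear")),
    }


# ---------------------------------------------------------------------------
# stepwise multi-QTL model selection
# ---------------------------------------------------------------------------

@dataclass
class QTLTerm:
    chrom: str
    pos_cM: float
    effect: float
    se: float
    interval: tuple[float, float]
    pve: float

    @property
    def label(self) -> str:
        return f"{self.chrom}@{self.pos_cM:.1f}"


@dataclass
class QTLModel:
    terms: list[QTLTerm] = field(default_factory=list)
    model_lod: float = 0.0
    total_pve: float = 0.0
    n_lines: int = 0
    converged: bool = True

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.label, t.chrom, t.pos_cM, t.effect, t.se, t.interval[0], t.interval[1], t.pve)
                for t in self.terms
            ],
            columns=["qtl", "chrom", "pos_cM", "effect", "se", "ci_lo_cM", "ci_hi_cM", "pve"],
        )


def _model_lod(y: np.ndarray, X: np.ndarray, idx: list[int]) -> float:
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if not idx:
        return 0.0
    lod, _, _ = _fit_lod(y, X[:, idx], rss0)
    return lod


def stepwise_select(
    phenotype,
    probgrid: ProbGrid,
    penalty: float,
    max_qtl: int = 10,
    max_iter: int = 30,
) -> QTLModel:
    """Forward–backward stepwise search for an additive multi-QTL model.

    Maximises the penalized LOD (model LOD minus ``penalty`` per QTL term).
    After convergence each term's position is refined by rescanning its
    chromosome with the other terms as covariates; effects, standard errors,
    1.5-LOD intervals and per-term PVE (from type-III drop LODs) come from
    the final joint fit.
    """
    y, keep = _align_phenotype(phenotype, probgrid)
    X, meta = probgrid.dosage_matrix()
    X = X[keep]
    y = y[keep]
    n = len(y)
    chosen: list[int] = []
    converged = True
    for _ in range(max_iter):
        changed = False
        # forward
        if len(chosen) < max_qtl:
            C = X[:, chosen] if chosen else None
            Q = _residualize(y, C)
            # conditional LOD of each candidate given the chosen terms:
            # (n/2)·log10(RSS_chosen / RSS_chosen+candidate)
            cond, _, _, _ = _scan_core(X, y, Q)
            best = int(np.argmax(cond))
            if cond[best] > penalty:
                chosen.append(best)
                changed = True
        # backward
        if chosen:
            full = _model_lod(y, X, chosen)
            worst, worst_drop = None, np.inf
            for t in list(chosen):
                rest = [c for c in chosen if c != t]
                drop = full - _model_lod(y, X, rest)
                if drop < worst_drop:
                    worst, worst_drop = t, drop
            if worst is not None and worst_drop < penalty:
                chosen.remove(worst)
                changed = True
        if not changed:
            break
    else:
        converged = False
    # position refinement: rescan each term's chromosome given the others
    for k, t in enumerate(list(chosen)):
        others = [c for c in chosen if c != t]
        C = X[:, others] if others else None
        Q = _residualize(y, C)
        lod_k, _, _, _ = _scan_core(X, y, Q)
        chrom_t = meta["chrom"].iat[t]
        on_chrom = np.flatnonzero((meta["chrom"] == chrom_t).to_numpy())
        chosen[k] = int(on_chrom[np.argmax(lod_k[on_chrom])])
    chosen = sorted(set(chosen))
    model = QTLModel(n_lines=n, converged=converged)
    if not chosen:
        return model
    # final joint fit
    A = np.column_stack([np.ones(n), X[:, chosen]])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(resid @ resid)
    dof = n - A.shape[1]
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.diag(cov))[1:]
    model.model_lod = _model_lod(y, X, chosen)
    model.total_pve = 100.0 * (1.0 - 10 ** (-2.0 * model.model_lod / n))
    for k, t in enumerate(chosen):
        rest = [c for c in chosen if c != t]
        drop_lod = model.model_lod - _model_lod(y, X, rest)
        pve = 100.0 * (1.0 - 10 ** (-2.0 * max(drop_lod, 0.0) / n))
        chrom_t = meta["chrom"].iat[t]
        # interval from the conditional scan of this chromosome
        C = X[:, rest] if rest else None
        Q = _residualize(y, C)
        lod_k, _, _, _ = _scan_core(X, y, Q)
        sub = meta.copy()
        sub["lod"] = lod_k
        ci = lod_interval(sub, chrom_t)
        model.terms.append(
            QTLTerm(
                chrom=chrom_t,
                pos_cM=round(float(meta["pos_cM"].iat[t]), 1),
                effect=float(coef[1 + k]),
                se=float(se[k]),
                interval=ci,
                pve=float(pve),
            )
        )
    return model


def fit_effects_at(
    phenotype,
    probgrid: ProbGrid,
    positions: list[tuple[str, float]],
) -> pd.DataFrame:
    """Joint additive fit at fixed grid positions (no peak search).

    Returns a frame with chrom, pos_cM, effect, se; used for forced-position
    effect re-estimation (e.g. per-date trajectories, cross-trait effects).
    """
    y, keep = _align_phenotype(phenotype, probgrid)
    X, meta = probgrid.dosage_matrix()
    idx = [probgrid.index_of(c, p) for c, p in positions]
    A = np.column_stack([np.ones(keep.sum()), X[np.ix_(keep, idx)]])
    yv = y[keep]
    coef, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    dof = len(yv) - A.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.diag(cov))[1:]
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in positions],
            "pos_cM": [meta["pos_cM"].iat[i] for i in idx],
            "effect": coef[1:],
            "se": se,
        }
    )
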
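"""QTL detection for a four-way-cross (F1 outbred) progeny.

Each individual of an F1 progeny between two heterozygous parents carries one
of four parental-haplotype combinations per locus, written ``ac``, ``ad``,
``bc`` and ``bd`` (first letter: allele inherited from parent 1, second from
parent 2).  A genome scan regresses a per-genotype trait value on the four
genotype-class probabilities at each marker and summarises the evidence as a
LOD score,

    LOD = (n / 2) * log10(RSS_0 / RSS_1),

the likelihood-ratio statistic of the 3-d.f. class model against the
intercept-only model under normal errors.  Genome-wide significance is
calibrated by permuting the phenotype; multi-QTL models are built stepwise
and summarised with drop-one (type III) LOD and percent-variance per locus;
QTL positions carry Bayesian credible intervals built from normalized
10^LOD profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("ac", "ad", "bc", "bd")
_CLASS_INDEX = {c: i for i, c in enumerate(GENOTYPE_CLASSES)}

#: default cap on the per-marker missing-data fraction
MAX_MISSING_FRACTION = 0.10


def haldane(d_cM):
    """Haldane map function: r = 0.5 * (1 - exp(-2 d / 100)) for d in cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


class GeneticMap:
    """Ordered marker map: name ("<chrom>_<bp>"), chromosome, cM and bp positions."""

    REQUIRED = ("marker", "chromosome", "position_cM", "position_bp")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"map table missing columns {missing}")
        table = table.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name {dup!r}")
        for chrom, sub in table.groupby("chromosome", sort=False):
            if not sub["position_cM"].is_monotonic_increasing:
                raise ValueError(f"cM positions not sorted on {chrom}")
            if not sub["position_bp"].is_monotonic_increasing:
                raise ValueError(f"bp positions not sorted on {chrom}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_table(self, chromosome) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"chromosome {chromosome!r} not in map")
        return sub

    def marker_row(self, marker: str) -> pd.Series:
        sub = self.table[self.table["marker"] == marker]
        if sub.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return sub.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path))


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype CSV (rows = individuals, columns = markers, NA = missing)."""
    geno = pd.read_csv(path, index_col=0, dtype=str)
    bad = set(np.unique(geno.fillna("ac").to_numpy())) - set(GENOTYPE_CLASSES)
    if bad:
        raise ValueError(f"unknown genotype classes {sorted(bad)}")
    return geno


def check_missingness(geno: pd.DataFrame, cap: float = MAX_MISSING_FRACTION) -> None:
    frac = geno.isna().mean(axis=0)
    over = frac[frac > cap]
    if len(over):
        raise ValueError(
            f"{len(over)} markers exceed the missing-data cap of {cap:.0%} "
            f"(worst: {over.idxmax()} at {over.max():.0%})")


def remove_duplicate_markers(geno: pd.DataFrame) -> pd.DataFrame:
    """Keep the first of any set of markers with identical genotype columns.

    Missing values are matched literally (no wildcard), so the result is
    deterministic and order-stable.
    """
    if geno.shape[1] < 1:
        raise ValueError("genotype matrix has no markers")
    seen: dict[tuple, str] = {}
    keep = []
    arr = geno.fillna("__NA__").to_numpy(dtype=str)
    for j, marker in enumerate(geno.columns):
        key = tuple(arr[:, j])
        if key not in seen:
            seen[key] = marker
            keep.append(marker)
    return geno.loc[:, keep]


# ---------------------------------------------------------------------------
# Genotype-class probabilities
# ---------------------------------------------------------------------------

def _parent_alleles(cls: str) -> tuple[int, int]:
    return (0 if cls[0] == "a" else 1, 0 if cls[1] == "c" else 1)


def _flank_prob(gl: int | None, dl: float, gr: int | None, dr: float) -> float:
    """P(allele = 0 at the target) for one parent given flanking alleles.

    ``gl``/``gr`` are the nearest informative alleles left/right (None if
    absent) at Haldane distances ``dl``/``dr``.  Follows from counting the
    recombination events in the two intervals.
    """
    if gl is None and gr is None:
        return 0.5
    if gr is None:
        rl = haldane(dl)
        return 1.0 - rl if gl == 0 else rl
    if gl is None:
        rr = haldane(dr)
        return 1.0 - rr if gr == 0 else rr
    rl, rr = haldane(dl), haldane(dr)
    # P(X = x | L, R) proportional to P(L -> x) * P(x -> R)
    p0 = (1.0 - rl if gl == 0 else rl) * (1.0 - rr if gr == 0 else rr)
    p1 = (rl if gl == 0 else 1.0 - rl) * (rr if gr == 0 else 1.0 - rr)
    return p0 / (p0 + p1)


def genotype_probabilities(
    geno: pd.DataFrame,
    gmap: GeneticMap,
    marker: str,
) -> np.ndarray:
    """(n, 4) genotype-class probabilities at a marker.

    Observed genotypes give indicator rows.  For missing entries the
    probabilities are reconstructed per parent independently from the nearest
    non-missing flanking markers on the chromosome via the Haldane map
    function; an individual with no informative marker on the chromosome gets
    the uniform 1/4 vector.  Rows always sum to 1.
    """
    row = gmap.marker_row(marker)
    chrom_tab = gmap.chrom_table(row["chromosome"])
    chrom_markers = [m for m in chrom_tab["marker"] if m in geno.columns]
    pos = {m: float(gmap.marker_row(m)["position_cM"]) for m in chrom_markers}
    target_pos = float(row["position_cM"])
    j = chrom_markers.index(marker)

    n = len(geno)
    probs = np.empty((n, 4))
    col = geno[marker].to_numpy(dtype=object)
    sub = geno.loc[:, chrom_markers].to_numpy(dtype=object)
    for i in range(n):
        cls = col[i]
        if isinstance(cls, str) and cls in _CLASS_INDEX:
            vec = np.zeros(4)
            vec[_CLASS_INDEX[cls]] = 1.0
            probs[i] = vec
            continue
        # nearest informative flanks for this individual
        gl = gr = None
        dl = dr = 0.0
        for k in range(j - 1, -1, -1):
            if isinstance(sub[i, k], str) and sub[i, k] in _CLASS_INDEX:
                gl = _parent_alleles(sub[i, k])
                dl = target_pos - pos[chrom_markers[k]]
                break
        for k in range(j + 1, len(chrom_markers)):
            if isinstance(sub[i, k], str) and sub[i, k] in _CLASS_INDEX:
                gr = _parent_alleles(sub[i, k])
                dr = pos[chrom_markers[k]] - target_pos
                break
        p1 = _flank_prob(None if gl is None else gl[0], dl,
                         None if gr is None else gr[0], dr)
        p2 = _flank_prob(None if gl is None else gl[1], dl,
                         None if gr is None else gr[1], dr)
        probs[i] = np.outer([p1, 1 - p1], [p2, 1 - p2]).ravel()
    return probs


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker LOD profile plus the permutation threshold used, if any."""

    table: pd.DataFrame  # marker, chromosome, position_cM, position_bp, lod
    threshold: float | None = None
    n_permutations: int = 0
    alpha: float = 0.05

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self, chromosome=None) -> pd.Series:
        tab = self.table
        if chromosome is not None:
            tab = tab[tab["chromosome"] == chromosome]
        return tab.loc[tab["lod"].idxmax()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class MarkerRegressionScanner:
    """Caches per-marker class probabilities and orthonormal design bases.

    Building the QR factor of each marker's (n, 4) probability matrix once
    makes repeated scans (permutations, stepwise refinement, many null
    traits) a single matrix product per marker.
    """

    def __init__(self, geno: pd.DataFrame, gmap: GeneticMap,
                 missing_cap: float = MAX_MISSING_FRACTION):
        markers = [m for m in gmap.table["marker"] if m in geno.columns]
        if not markers:
            raise ValueError("no map markers present in the genotype matrix")
        check_missingness(geno.loc[:, markers], cap=missing_cap)
        self.geno = geno
        self.gmap = gmap
        self.markers = markers
        self.map_rows = gmap.table.set_index("marker").loc[markers]
        self.n = len(geno)
        self._probs: dict[str, np.ndarray] = {}
        self._basis: list[np.ndarray] = []
        missing_any = geno.loc[:, markers].isna().to_numpy()
        classes = geno.loc[:, markers].to_numpy(dtype=object)
        for j, m in enumerate(markers):
            if missing_any[:, j].any():
                X = genotype_probabilities(geno, gmap, m)
            else:
                X = np.zeros((self.n, 4))
                idx = [_CLASS_INDEX[c] for c in classes[:, j]]
                X[np.arange(self.n), idx] = 1.0
            self._probs[m] = X
            q, r = np.linalg.qr(X)
            keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
            self._basis.append(q[:, keep])

    def probabilities(self, marker: str) -> np.ndarray:
        return self._probs[marker]

    def lod_matrix(self, Y: np.ndarray) -> np.ndarray:
        """(n_markers, n_traits) LOD scores for trait columns of Y (n, m)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = Y.shape[0]
        yty = np.sum(Y * Y, axis=0)
        rss0 = yty - n * np.mean(Y, axis=0) ** 2
        lod = np.empty((len(self.markers), Y.shape[1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            for j, Q in enumerate(self._basis):
                proj = Q.T @ Y
                rss1 = yty - np.sum(proj * proj, axis=0)
                # a residual below numerical precision is a perfect fit
                rss1 = np.where(rss1 <= 1e-12 * rss0, 0.0, rss1)
                lod[j] = 0.5 * n * np.log10(rss0 / rss1)
        lod[:, rss0 <= 1e-12 * max(1.0, float(yty.max(initial=0.0)))] = 0.0
        lod = np.where(np.isnan(lod), 0.0, lod)
        return np.maximum(lod, 0.0)

    def scan(self, phenotype: np.ndarray) -> np.ndarray:
        return self.lod_matrix(np.asarray(phenotype, float))[:, 0]


def _align(phenotype: pd.Series, geno: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    if isinstance(phenotype, pd.Series):
        common = phenotype.index.intersection(geno.index)
        if len(common) < len(phenotype):
            logger.info("dropping %d phenotyped individuals without genotypes",
                        len(phenotype) - len(common))
        return phenotype.loc[common].to_numpy(float), geno.loc[common]
    y = np.asarray(phenotype, float)
    if len(y) != len(geno):
        raise ValueError("phenotype length does not match genotype matrix")
    return y, geno


def scan_lod(phenotype, geno: pd.DataFrame, gmap: GeneticMap,
             scanner: MarkerRegressionScanner | None = None) -> ScanResult:
    """One-dimensional genome scan by marker regression on class probabilities."""
    y, geno_a = _align(phenotype, geno)
    if len(y) < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    if scanner is None or len(scanner.geno) != len(geno_a):
        scanner = MarkerRegressionScanner(geno_a, gmap)
    if np.var(y) == 0:
        warnings.warn("phenotype is constant; all LOD scores are zero")
    lod = scanner.scan(y)
    if np.isinf(lod).any():
        warnings.warn("perfect fit at some markers (RSS = 0); LOD reported as inf")
    tab = scanner.map_rows.reset_index()[
        ["marker", "chromosome", "position_cM", "position_bp"]].copy()
    tab["lod"] = lod
    return ScanResult(tab)


def permutation_threshold(
    phenotype,
    geno: pd.DataFrame,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scanner: MarkerRegressionScanner | None = None,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The empirical (1 - alpha) quantile (linear / type-7 interpolation) of the
    genome-wide maximum LOD over ``n_perm`` random phenotype shuffles.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y, geno_a = _align(phenotype, geno)
    if scanner is None or len(scanner.geno) != len(geno_a):
        scanner = MarkerRegressionScanner(geno_a, gmap)
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    max_lod = scanner.lod_matrix(Y).max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha))


# ---------------------------------------------------------------------------
# Credible intervals
# ---------------------------------------------------------------------------

@dataclass
class CredibleInterval:
    chromosome: object
    low_cM: float
    low_bp: int
    peak_marker: str
    peak_cM: float
    peak_bp: int
    high_cM: float
    high_bp: int
    coverage: float

    def contains_cM(self, position_cM: float) -> bool:
        return self.low_cM <= position_cM <= self.high_cM

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome, "low_cM": self.low_cM,
            "low_bp": int(self.low_bp), "peak_marker": self.peak_marker,
            "peak_cM": self.peak_cM, "peak_bp": int(self.peak_bp),
            "high_cM": self.high_cM, "high_bp": int(self.high_bp),
            "coverage": self.coverage,
        }


def bayes_credible_interval(scan: ScanResult, chromosome,
                            coverage: float = 0.95) -> CredibleInterval:
    """Bayesian credible interval for a QTL peak on one chromosome.

    Marker weights 10^LOD are normalized over the chromosome; markers are
    accumulated in decreasing weight order (starting at the peak) until the
    target coverage is reached, and the interval spans the accumulated set.
    Reported bounds are marker positions in both cM and bp.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    tab = scan.table[scan.table["chromosome"] == chromosome].reset_index(drop=True)
    if tab.empty:
        raise KeyError(f"chromosome {chromosome!r} not scanned")
    lod = tab["lod"].to_numpy(float)
    finite = np.isfinite(lod)
    if finite.any() and not finite.all():
        lod = np.where(finite, lod, lod[finite].max() + 50.0)  # inf peaks dominate
    if np.all(lod <= 0):
        warnings.warn("flat zero LOD profile; credible interval spans the chromosome")
        weights = np.full(len(tab), 1.0 / len(tab))
    else:
        w = np.power(10.0, lod - lod.max())
        weights = w / w.sum()
    order = np.argsort(-weights, kind="stable")
    cum = 0.0
    chosen = []
    for idx in order:
        chosen.append(idx)
        cum += weights[idx]
        if cum >= coverage:
            break
    lo, hi = min(chosen), max(chosen)
    peak = tab.iloc[int(order[0])]
    return CredibleInterval(
        chromosome,
        float(tab["position_cM"].iloc[lo]), int(tab["position_bp"].iloc[lo]),
        str(peak["marker"]), float(peak["position_cM"]), int(peak["position_bp"]),
        float(tab["position_cM"].iloc[hi]), int(tab["position_bp"].iloc[hi]),
        coverage,
    )


# ---------------------------------------------------------------------------
# Multi-QTL models
# ---------------------------------------------------------------------------

@dataclass
class QtlLocus:
    chromosome: object
    marker: str
    position_cM: float
    position_bp: int
    lod: float
    pct_var: float
    interval: CredibleInterval | None = None

    def to_dict(self) -> dict:
        d = {
            "chromosome": self.chromosome, "marker": self.marker,
            "position_cM": self.position_cM, "position_bp": int(self.position_bp),
            "lod": self.lod, "pct_var": self.pct_var,
        }
        if self.interval is not None:
            d["interval"] = self.interval.to_dict()
        return d


@dataclass
class QtlModel:
    loci: list[QtlLocus] = field(default_factory=list)
    overall_lod: float = 0.0
    overall_pct_var: float = 0.0
    n: int = 0
    threshold: float | None = None

    @property
    def markers(self) -> list[str]:
        return [l.marker for l in self.loci]

    def to_dict(self) -> dict:
        return {
            "loci": [l.to_dict() for l in self.loci],
            "overall_lod": self.overall_lod,
            "overall_pct_var": self.overall_pct_var,
            "n": self.n,
            "threshold": self.threshold,
        }


def _design(scanner: MarkerRegressionScanner, markers: Sequence[str],
            n: int) -> np.ndarray:
    """Intercept + 3 class-contrast columns per locus (first class dropped)."""
    cols = [np.ones((n, 1))]
    for m in markers:
        cols.append(scanner.probabilities(m)[:, 1:])
    return np.hstack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2))


def fit_multi_qtl_model(
    phenotype,
    geno: pd.DataFrame,
    gmap: GeneticMap,
    loci: Sequence[str],
    scanner: MarkerRegressionScanner | None = None,
) -> QtlModel:
    """Additive multi-locus model with drop-one (type III) LOD and %variance.

    The full model regresses the trait on the class probabilities of every
    locus jointly.  Each locus is summarised by the fit lost when it alone is
    dropped: LOD = (n/2) log10(RSS_reduced / RSS_full) and
    %var = 100 (RSS_reduced - RSS_full) / TSS.  Overall LOD and %var compare
    the full model to the intercept-only model.
    """
    loci = list(loci)
    if len(set(loci)) != len(loci):
        raise ValueError("loci must be distinct markers")
    y, geno_a = _align(phenotype, geno)
    if scanner is None or len(scanner.geno) != len(geno_a):
        scanner = MarkerRegressionScanner(geno_a, gmap)
    for a in loci:
        for b in loci:
            if a != b and np.allclose(scanner.probabilities(a),
                                      scanner.probabilities(b)):
                raise ValueError(f"loci {a!r} and {b!r} are collinear")
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    X_full = _design(scanner, loci, n)
    rss_full = _rss(X_full, y)
    model = QtlModel(n=n)
    if tss <= 0:
        warnings.warn("constant phenotype; empty model")
        return model
    for m in loci:
        others = [o for o in loci if o != m]
        rss_red = _rss(_design(scanner, others, n), y)
        with np.errstate(divide="ignore"):
            lod = 0.5 * n * np.log10(rss_red / rss_full) if rss_full > 0 else np.inf
        row = gmap.marker_row(m)
        model.loci.append(QtlLocus(
            row["chromosome"], m, float(row["position_cM"]),
            int(row["position_bp"]), float(lod),
            100.0 * (rss_red - rss_full) / tss))
    with np.errstate(divide="ignore"):
        model.overall_lod = float(0.5 * n * np.log10(tss / rss_full)) \
            if rss_full > 0 else np.inf
    model.overall_pct_var = 100.0 * (tss - rss_full) / tss
    return model


def _model_residuals(scanner, loci, y):
    if not loci:
        return y - y.mean()
    X = _design(scanner, loci, len(y))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def stepwise_model_search(
    phenotype,
    geno: pd.DataFrame,
    gmap: GeneticMap,
    threshold: float,
    max_qtl: int = 10,
    coverage: float = 0.95,
    scanner: MarkerRegressionScanner | None = None,
) -> QtlModel:
    """Stepwise additive QTL-model construction.

    Iteratively scans the residuals of the current model, adds the best
    candidate locus if its drop-one LOD in the joint model strictly exceeds
    the (permutation-derived) threshold, then refines every locus position to
    the best marker on its chromosome holding the others fixed.  Stops when
    no candidate qualifies; interactions are not searched.  Each retained
    locus gets a Bayesian credible interval from the scan of the trait with
    the other loci's fitted contributions removed.
    """
    y, geno_a = _align(phenotype, geno)
    if scanner is None or len(scanner.geno) != len(geno_a):
        scanner = MarkerRegressionScanner(geno_a, gmap)
    loci: list[str] = []
    map_tab = scanner.map_rows

    def scan_table(resid):
        tab = map_tab.reset_index()[
            ["marker", "chromosome", "position_cM", "position_bp"]].copy()
        tab["lod"] = scanner.scan(resid)
        return ScanResult(tab)

    while len(loci) < max_qtl:
        resid = _model_residuals(scanner, loci, y)
        res = scan_table(resid)
        cand_tab = res.table[~res.table["marker"].isin(loci)]
        if cand_tab.empty:
            break
        cand = str(cand_tab.loc[cand_tab["lod"].idxmax(), "marker"])
        trial = fit_multi_qtl_model(y, geno_a, gmap, loci + [cand], scanner=scanner)
        drop_one = next(l.lod for l in trial.loci if l.marker == cand)
        if not drop_one > threshold:
            break
        loci.append(cand)
        # refine: move each locus to the best marker on its chromosome
        for i, m in enumerate(loci):
            chrom = gmap.marker_row(m)["chromosome"]
            others = [o for j, o in enumerate(loci) if j != i]
            resid_i = _model_residuals(scanner, others, y)
            res_i = scan_table(resid_i)
            sub = res_i.table[(res_i.table["chromosome"] == chrom)
                              & ~res_i.table["marker"].isin(others)]
            best = str(sub.loc[sub["lod"].idxmax(), "marker"])
            loci[i] = best

    model = fit_multi_qtl_model(y, geno_a, gmap, loci, scanner=scanner) \
        if loci else QtlModel(n=len(y))
    model.threshold = threshold
    for locus in model.loci:
        others = [o for o in model.markers if o != locus.marker]
        resid = _model_residuals(scanner, others, y)
        tab = map_tab.reset_index()[
            ["marker", "chromosome", "position_cM", "position_bp"]].copy()
        tab["lod"] = scanner.scan(resid)
        locus.interval = bayes_credible_interval(
            ScanResult(tab), locus.chromosome, coverage)
    return model
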
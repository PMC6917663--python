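"""Linkage map construction and QTL scanning for an F2 intercross.

The workflow mirrors a classical biparental QTL study: codominant marker
genotypes (AA / AB / BB) on a physically ordered marker set are turned into a
genetic map by maximum-likelihood estimation of adjacent recombination
fractions; conditional QTL genotype probabilities on a cM grid are computed
with a three-state hidden Markov model; and the family-mean phenotype is
regressed on the expected additive and dominance predictors at every grid
position (Haley-Knott regression), giving a LOD profile. Genome-wide
significance comes from phenotype permutations, and QTL location uncertainty
from LOD-drop support intervals.

State convention: 0 = AA (homozygous for the tolerant-parent allele),
1 = AB, 2 = BB (sensitive-parent homozygote); missing genotypes are -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapfun import get_map_function

__all__ = [
    "CODE_TO_INT",
    "INT_TO_CODE",
    "GeneticMap",
    "GenotypeMatrix",
    "ScanConfig",
    "GenotypeProbabilities",
    "ScanResult",
    "SupportInterval",
    "QTLReport",
    "estimate_rf",
    "build_map",
    "map_summary",
    "MapSummary",
    "polymorphism_rate",
    "genotype_probabilities",
    "scan_im",
    "scan_cim",
    "select_cofactors",
    "permutation_threshold",
    "null_scan_calibration",
    "support_interval",
    "report_qtls",
    "lod_to_r2",
]

CODE_TO_INT = {"AA": 0, "AB": 1, "BB": 2}
INT_TO_CODE = {0: "AA", 1: "AB", 2: "BB", -1: "NA"}

#: F2 prior on {AA, AB, BB} under Mendelian segregation.
F2_PRIOR = np.array([0.25, 0.5, 0.25])


# ---------------------------------------------------------------------------
# containers


@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome, cM and bp position.

    Within each chromosome cM must be non-decreasing and must sort the
    markers in the same order as bp — the map-validity criterion used to
    accept a physically anchored map for scanning.
    """

    markers: pd.DataFrame  # columns: marker_id, chrom, cm, bp

    def __post_init__(self):
        required = {"marker_id", "chrom", "cm", "bp"}
        missing = required - set(self.markers.columns)
        if missing:
            raise ValueError(f"genetic map lacks columns {sorted(missing)}")
        self.markers = self.markers.reset_index(drop=True)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(float)
            bp = sub["bp"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on chromosome {chrom}")
            if np.any(np.diff(bp) < 0):
                raise ValueError(
                    f"marker order on chromosome {chrom} is inconsistent with bp "
                    "positions (cM order must equal physical order)"
                )

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_markers(self, chrom) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def to_csv(self, path):
        self.markers.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, dtype={"marker_id": str, "chrom": str}))


@dataclass
class GenotypeMatrix:
    """F2 marker genotypes, individuals x markers, coded 0/1/2 with -1 missing."""

    individual_ids: list
    marker_ids: list
    codes: np.ndarray  # int8 (n_individuals, n_markers)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise ValueError("genotype matrix dimensions do not match id lists")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes restricted to {AA, AB, BB, missing}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    def column(self, marker_id) -> np.ndarray:
        return self.codes[:, self.marker_ids.index(marker_id)]

    def to_frame(self) -> pd.DataFrame:
        data = np.vectorize(INT_TO_CODE.get)(self.codes)
        return pd.DataFrame(data, index=self.individual_ids, columns=self.marker_ids)

    def to_csv(self, path):
        df = self.to_frame()
        df.index.name = "individual_id"
        df.to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        mapping = dict(CODE_TO_INT)
        mapping.update({"NA": -1, "": -1})
        codes = np.full(df.shape, -1, dtype=np.int8)
        values = df.to_numpy()
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                v = values[i, j]
                if isinstance(v, float) and np.isnan(v):
                    codes[i, j] = -1
                    continue
                key = str(v).strip()
                if key not in mapping:
                    raise ValueError(f"unknown genotype code {v!r}")
                codes[i, j] = mapping[key]
        return cls(list(df.index), list(df.columns), codes)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col="individual_id", dtype=str)
        return cls.from_frame(df)


@dataclass
class ScanConfig:
    """Tuning knobs for map building, genotype probabilities and scanning."""

    step_cm: float = 1.0
    error_rate: float = 0.001
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 2.0
    cofactor_window_cm: float = 10.0
    max_cofactors: int = 5
    map_function: str = "haldane"
    max_gap_cm: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.step_cm <= 0:
            raise ValueError("grid step must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("genotyping error rate must lie in [0, 0.5)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class GenotypeProbabilities:
    """Conditional genotype probabilities on the scan grid.

    ``probs[i, p, s]`` is P(state s at grid position p | all marker data of
    individual i). Grid positions are the union of marker locations and a
    regular cM lattice, concatenated over chromosomes.
    """

    individual_ids: list
    chrom: np.ndarray  # (P,) chromosome label per grid position
    cm: np.ndarray  # (P,)
    probs: np.ndarray  # (n, P, 3)

    @property
    def n_positions(self) -> int:
        return len(self.cm)

    def additive_dominance(self) -> tuple[np.ndarray, np.ndarray]:
        """Haley-Knott predictors: x_a = P(AA) - P(BB), x_d = P(AB)."""
        xa = self.probs[:, :, 0] - self.probs[:, :, 2]
        xd = self.probs[:, :, 1]
        return xa, xd

    def chrom_slices(self) -> list[tuple[object, slice]]:
        out = []
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                out.append((self.chrom[start], slice(start, i)))
                start = i
        return out


@dataclass
class ScanResult:
    """LOD profile with per-position effect estimates."""

    chrom: np.ndarray
    cm: np.ndarray
    lod: np.ndarray
    add_effect: np.ndarray
    dom_effect: np.ndarray
    r2: np.ndarray  # percent variance explained by the QTL terms
    n_individuals: int
    kind: str = "im"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "cm": self.cm,
                "lod": self.lod,
                "a": self.add_effect,
                "d": self.dom_effect,
                "r2": self.r2,
            }
        )

    def peak(self) -> int:
        """Index of the global LOD maximum (leftmost on ties)."""
        return int(np.argmax(self.lod))


@dataclass
class SupportInterval:
    chrom: object
    left_cm: float
    right_cm: float
    left_marker: str
    right_marker: str

    def contains(self, cm: float) -> bool:
        return self.left_cm - 1e-9 <= cm <= self.right_cm + 1e-9


@dataclass
class QTLReport:
    name: str
    experiment: str
    chrom: object
    peak_cm: float
    peak_lod: float
    interval: SupportInterval
    r2_pct: float
    repeatedly_detected: bool = False


@dataclass
class MapSummary:
    total_cm: float
    mean_interval_cm: float
    markers_per_chrom: dict = field(default_factory=dict)
    n_markers: int = 0


# ---------------------------------------------------------------------------
# recombination fraction estimation and map building


def _two_locus_class_probs(r: float) -> np.ndarray:
    """P(two-locus genotype class, k recombinant gametes) for an F2.

    Returns an array ``p[g1, g2, k]`` over the nine genotype classes
    (each locus coded 0/1/2) and k in {0, 1, 2}. Gametes from the coupling
    F1 carry a recombination indicator; each F2 individual is the union of
    two independent gametes.
    """
    # gamete: (allele at locus 1, allele at locus 2, recombinant?, probability)
    gametes = [
        (0, 0, 0, (1 - r) / 2),
        (0, 1, 1, r / 2),
        (1, 0, 1, r / 2),
        (1, 1, 0, (1 - r) / 2),
    ]
    p = np.zeros((3, 3, 3))
    for a1, a2, k1, p1 in gametes:
        for b1, b2, k2, p2 in gametes:
            p[a1 + b1, a2 + b2, k1 + k2] += p1 * p2
    return p


def estimate_rf(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Maximum-likelihood recombination fraction between two F2 marker columns.

    EM over the nine observable two-locus genotype classes: the hidden
    quantity is the number of recombinant gametes (0, 1 or 2) carried by each
    individual, which is ambiguous for several classes (most notably the
    double heterozygote, a mixture of zero- and two-recombinant phases).
    Individuals missing either call are dropped.
    """
    a = np.asarray(geno_a)
    b = np.asarray(geno_b)
    keep = (a >= 0) & (b >= 0)
    if keep.sum() < 2:
        raise ValueError("need at least two individuals genotyped at both markers")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a[keep], b[keep]), 1.0)
    n_gametes = 2.0 * counts.sum()

    r = 0.25
    for _ in range(max_iter):
        p = _two_locus_class_probs(r)
        class_p = p.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            # expected recombinant gametes per individual of each class
            e_k = (p * np.arange(3)).sum(axis=2) / class_p
        e_k = np.nan_to_num(e_k)
        r_new = float((counts * e_k).sum() / n_gametes)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return r


def two_locus_loglik(counts: np.ndarray, r: float) -> float:
    """Multinomial log-likelihood of a 3x3 two-locus count table at a given r."""
    class_p = _two_locus_class_probs(r).sum(axis=2)
    with np.errstate(divide="ignore"):
        ll = counts * np.log(class_p)
    return float(ll[counts > 0].sum())


def build_map(
    genotypes: GenotypeMatrix,
    marker_info: pd.DataFrame,
    config: ScanConfig | None = None,
) -> GeneticMap:
    """Genetic map from genotypes and physical marker order.

    Marker order is fixed to the physical (bp) order — the map is validated
    against physical position, never searched. Adjacent recombination
    fractions are estimated by EM and converted to cM with the inverse map
    function, accumulating along each chromosome from 0. Adjacent pairs that
    appear unlinked (r -> 0.5) would give unbounded distances; those gaps are
    capped at ``config.max_gap_cm`` with a warning.

    Parameters
    ----------
    marker_info
        Columns ``marker_id``, ``chrom``, ``bp`` for every genotyped marker.
    """
    config = config or ScanConfig()
    _, to_cm = get_map_function(config.map_function)
    rows = []
    info = marker_info.sort_values(["chrom", "bp"], kind="stable")
    for chrom, sub in info.groupby("chrom", sort=False):
        ids = list(sub["marker_id"])
        bps = list(sub["bp"])
        cm = 0.0
        rows.append((ids[0], chrom, 0.0, bps[0]))
        for left, right, bp in zip(ids, ids[1:], bps[1:]):
            r = estimate_rf(genotypes.column(left), genotypes.column(right))
            d = float(to_cm(min(r, 0.4999)))
            if r >= 0.4999 or not np.isfinite(d) or d > config.max_gap_cm:
                warnings.warn(
                    f"adjacent markers {left}-{right} on {chrom} appear unlinked "
                    f"(r={r:.3f}); capping gap at {config.max_gap_cm} cM",
                    stacklevel=2,
                )
                d = config.max_gap_cm
            cm += d
            rows.append((right, chrom, cm, bp))
    return GeneticMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "cm", "bp"]))


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Total map length, mean inter-marker distance and markers per chromosome.

    The mean distance is total length divided by the number of markers (the
    convention under which 190 markers spanning 990.8 cM average 5.2 cM).
    """
    if gmap.markers.empty:
        raise ValueError("empty genetic map")
    per_chrom = {}
    total = 0.0
    for chrom, sub in gmap.markers.groupby("chrom", sort=False):
        per_chrom[chrom] = len(sub)
        total += float(sub["cm"].max() - sub["cm"].min())
    n = len(gmap.markers)
    return MapSummary(
        total_cm=total,
        mean_interval_cm=total / n,
        markers_per_chrom=per_chrom,
        n_markers=n,
    )


def polymorphism_rate(n_polymorphic: int, n_screened: int) -> float:
    """Percentage of screened markers polymorphic between the parents."""
    if n_screened <= 0 or n_polymorphic < 0 or n_polymorphic > n_screened:
        raise ValueError("invalid marker counts")
    return 100.0 * n_polymorphic / n_screened


# ---------------------------------------------------------------------------
# hidden-state genotype probabilities


def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix between linked loci (two meioses)."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def genotype_probabilities(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: ScanConfig | None = None,
) -> GenotypeProbabilities:
    """Forward-backward conditional genotype probabilities on the scan grid.

    The grid on each chromosome is the union of the marker positions and a
    regular lattice at ``config.step_cm``. Emissions at a marker give weight
    1 - eps to the observed code and eps/2 to each other state; missing calls
    (and pseudomarker grid points) are uninformative. The stationary F2 prior
    (1/4, 1/2, 1/4) initialises each chromosome.
    """
    config = config or ScanConfig()
    to_r, _ = get_map_function(config.map_function)
    eps = config.error_rate
    n = genotypes.n_individuals
    marker_index = {m: j for j, m in enumerate(genotypes.marker_ids)}

    all_chrom, all_cm, all_probs = [], [], []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_markers(chrom)
        mcm = sub["cm"].to_numpy(float)
        lattice = np.arange(mcm.min(), mcm.max() + config.step_cm / 2, config.step_cm)
        grid = np.unique(np.round(np.concatenate([mcm, lattice]), 9))
        n_pos = len(grid)

        # emission table (n, P, 3); product over markers sharing a position
        emis = np.ones((n, n_pos, 3))
        pos_of = {c: p for p, c in enumerate(grid)}
        for mid, cm in zip(sub["marker_id"], np.round(mcm, 9)):
            obs = genotypes.codes[:, marker_index[mid]]
            e = np.full((n, 3), 1.0)
            called = obs >= 0
            e[called] = eps / 2
            e[called, obs[called]] = 1.0 - eps
            emis[:, pos_of[cm], :] *= e

        trans = [_transition(float(to_r(d))) for d in np.diff(grid)]

        alpha = np.empty((n, n_pos, 3))
        alpha[:, 0] = F2_PRIOR * emis[:, 0]
        alpha[:, 0] /= alpha[:, 0].sum(axis=1, keepdims=True)
        for p in range(1, n_pos):
            alpha[:, p] = (alpha[:, p - 1] @ trans[p - 1]) * emis[:, p]
            alpha[:, p] /= alpha[:, p].sum(axis=1, keepdims=True)

        beta = np.ones((n, n_pos, 3))
        for p in range(n_pos - 2, -1, -1):
            beta[:, p] = (beta[:, p + 1] * emis[:, p + 1]) @ trans[p].T
            beta[:, p] /= beta[:, p].sum(axis=1, keepdims=True)

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)

        all_chrom.append(np.repeat(np.asarray(chrom, dtype=object), n_pos))
        all_cm.append(grid)
        all_probs.append(post)

    return GenotypeProbabilities(
        individual_ids=list(genotypes.individual_ids),
        chrom=np.concatenate(all_chrom),
        cm=np.concatenate(all_cm),
        probs=np.concatenate(all_probs, axis=1),
    )


# ---------------------------------------------------------------------------
# Haley-Knott scans


def _fit_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _phenotype_vector(phenotype, individual_ids) -> np.ndarray:
    """Align a phenotype (Series keyed by individual id, or array) to the probs."""
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(individual_ids).to_numpy(float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != len(individual_ids):
            raise ValueError("phenotype length does not match individuals")
    return y


def scan_im(
    probs: GenotypeProbabilities,
    phenotype,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Interval-mapping scan by Haley-Knott regression.

    At each grid position the phenotype is regressed on the expected additive
    predictor x_a = P(AA) - P(BB) and dominance predictor x_d = P(AB);
    LOD = (n/2) * log10(RSS0 / RSS1) against the intercept-only null.
    Individuals with missing phenotype are dropped.
    """
    config = config or ScanConfig()
    y = _phenotype_vector(phenotype, probs.individual_ids)
    keep = np.isfinite(y)
    y = y[keep]
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 phenotyped individuals, got {n}")
    xa, xd = probs.additive_dominance()
    xa, xd = xa[keep], xd[keep]

    rss0 = float(np.sum((y - y.mean()) ** 2))
    P = probs.n_positions
    lod = np.zeros(P)
    a_hat = np.zeros(P)
    d_hat = np.zeros(P)
    r2 = np.zeros(P)
    if rss0 == 0.0:
        warnings.warn("constant phenotype: LOD is identically zero", stacklevel=2)
    else:
        ones = np.ones(n)
        for p in range(P):
            X = np.column_stack([ones, xa[:, p], xd[:, p]])
            beta, rss1 = _fit_rss(X, y)
            lod[p] = max(0.0, (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300)))
            a_hat[p] = beta[1]
            d_hat[p] = beta[2]
            r2[p] = 100.0 * (1.0 - rss1 / rss0)
    return ScanResult(
        chrom=probs.chrom.copy(),
        cm=probs.cm.copy(),
        lod=lod,
        add_effect=a_hat,
        dom_effect=d_hat,
        r2=r2,
        n_individuals=n,
        kind="im",
    )


def _cofactor_design(
    genotypes: GenotypeMatrix, cofactors: Sequence[str]
) -> tuple[np.ndarray, list[str], dict]:
    """Additive + dominance codings for cofactor markers, mean-imputed."""
    cols, names = [], []
    for mid in cofactors:
        g = genotypes.column(mid).astype(float)
        g[g < 0] = np.nan
        xa = g - 1.0
        xd = (g == 1.0).astype(float)
        xd[np.isnan(g)] = np.nan
        for x, suffix in ((xa, "a"), (xd, "d")):
            x = np.where(np.isnan(x), np.nanmean(x), x)
            cols.append(x)
            names.append(f"{mid}:{suffix}")
    X = np.column_stack(cols) if cols else np.empty((genotypes.n_individuals, 0))
    return X, names, {}


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    if X.shape[1] == 0:
        return X, names
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear cofactor column {names[j]}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def scan_cim(
    probs: GenotypeProbabilities,
    phenotype,
    cofactors: Sequence[str],
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Composite-interval-mapping style scan.

    Identical to :func:`scan_im` but with cofactor marker genotypes as
    covariates in both the null and the full model; cofactors within
    ``config.cofactor_window_cm`` of the test position (same chromosome) are
    excluded so the tested interval is not absorbed by its own cofactor.
    With an empty cofactor set this reduces exactly to interval mapping.
    """
    config = config or ScanConfig()
    if not cofactors:
        result = scan_im(probs, phenotype, config)
        result.kind = "cim"
        return result

    y = _phenotype_vector(phenotype, probs.individual_ids)
    keep = np.isfinite(y)
    y = y[keep]
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 phenotyped individuals, got {n}")
    xa, xd = probs.additive_dominance()
    xa, xd = xa[keep], xd[keep]

    cof_X, cof_names, _ = _cofactor_design(genotypes, cofactors)
    cof_X = cof_X[keep]
    cof_X, cof_names = _drop_collinear(cof_X, cof_names)
    marker_pos = gmap.markers.set_index("marker_id")
    cof_loc = {
        name: (marker_pos.loc[name.split(":")[0], "chrom"],
               float(marker_pos.loc[name.split(":")[0], "cm"]))
        for name in cof_names
    }

    tss = float(np.sum((y - y.mean()) ** 2))
    P = probs.n_positions
    lod = np.zeros(P)
    a_hat = np.zeros(P)
    d_hat = np.zeros(P)
    r2 = np.zeros(P)
    ones = np.ones(n)
    if tss == 0.0:
        warnings.warn("constant phenotype: LOD is identically zero", stacklevel=2)
    else:
        for p in range(P):
            chrom_p, cm_p = probs.chrom[p], probs.cm[p]
            use = [
                j
                for j, name in enumerate(cof_names)
                if not (
                    cof_loc[name][0] == chrom_p
                    and abs(cof_loc[name][1] - cm_p) <= config.cofactor_window_cm
                )
            ]
            X0 = np.column_stack([ones, cof_X[:, use]]) if use else ones[:, None]
            X1 = np.column_stack([X0, xa[:, p], xd[:, p]])
            _, rss0 = _fit_rss(X0, y)
            beta1, rss1 = _fit_rss(X1, y)
            lod[p] = max(0.0, (n / 2.0) * np.log10(max(rss0, 1e-300) / max(rss1, 1e-300)))
            a_hat[p] = beta1[-2]
            d_hat[p] = beta1[-1]
            r2[p] = 100.0 * (rss0 - rss1) / tss
    return ScanResult(
        chrom=probs.chrom.copy(),
        cm=probs.cm.copy(),
        lod=lod,
        add_effect=a_hat,
        dom_effect=d_hat,
        r2=r2,
        n_individuals=n,
        kind="cim",
    )


def select_cofactors(
    genotypes: GenotypeMatrix,
    phenotype,
    config: ScanConfig | None = None,
) -> list[str]:
    """Forward selection of cofactor markers by BIC.

    Each marker enters as an additive + dominance pair (2 df). Selection
    stops when adding the best remaining marker no longer lowers BIC, or at
    ``config.max_cofactors``.
    """
    config = config or ScanConfig()
    if config.max_cofactors <= 0:
        return []
    y = _phenotype_vector(phenotype, genotypes.individual_ids)
    keep = np.isfinite(y)
    y = y[keep]
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 phenotyped individuals")

    def bic(rss: float, k: int) -> float:
        return n * np.log(max(rss, 1e-300) / n) + k * np.log(n)

    selected: list[str] = []
    X_sel = np.ones((n, 1))
    _, rss = _fit_rss(X_sel, y)
    current = bic(rss, 1)
    remaining = list(genotypes.marker_ids)
    while remaining and len(selected) < config.max_cofactors:
        best = None
        for mid in remaining:
            Xm, _, _ = _cofactor_design(genotypes, [mid])
            X = np.column_stack([X_sel, Xm[keep]])
            _, rss = _fit_rss(X, y)
            score = bic(rss, X.shape[1])
            if best is None or score < best[0]:
                best = (score, mid, X)
        if best is None or best[0] >= current:
            break
        current, mid, X_sel = best
        selected.append(mid)
        remaining.remove(mid)
    return selected


# ---------------------------------------------------------------------------
# permutations


class _FastScanner:
    """Precomputed per-position orthonormal bases for repeated max-LOD scans.

    For each grid position the column space of [1, x_a, x_d] is captured by
    an SVD basis (rank-deficient positions keep only their true rank), so the
    residual sum of squares for any phenotype vector is
    ||y||^2 - ||U' y||^2, and a whole-genome max-LOD costs one einsum.
    """

    def __init__(self, probs: GenotypeProbabilities, keep: np.ndarray):
        xa, xd = probs.additive_dominance()
        xa, xd = xa[keep], xd[keep]
        n = xa.shape[0]
        self.n = n
        P = probs.n_positions
        bases = np.zeros((P, n, 3))
        ones = np.ones(n)
        for p in range(P):
            X = np.column_stack([ones, xa[:, p], xd[:, p]])
            U, s, _ = np.linalg.svd(X, full_matrices=False)
            rank = int(np.sum(s > s[0] * 1e-10))
            bases[p, :, :rank] = U[:, :rank]
        self.bases = bases
        # basis of the intercept alone, for the null RSS
        self.mean_basis = ones / np.sqrt(n)

    def max_lod(self, y: np.ndarray) -> float:
        yy = float(y @ y)
        rss0 = yy - float(self.mean_basis @ y) ** 2
        if rss0 <= 0:
            return 0.0
        proj = np.einsum("pnk,n->pk", self.bases, y)
        rss1 = np.maximum(yy - np.einsum("pk,pk->p", proj, proj), 1e-300)
        return float(np.max((self.n / 2.0) * np.log10(rss0 / rss1)))


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotype,
    config: ScanConfig | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype labels are shuffled ``config.n_permutations`` times (seeded by
    ``config.seed``); the threshold is the empirical (1 - alpha) quantile of
    the permutation maxima, taken as the next order statistic at or above
    that level (the conservative choice for a permutation test).
    """
    config = config or ScanConfig()
    if config.n_permutations < 20:
        raise ValueError("need at least 20 permutations for a meaningful threshold")
    y = _phenotype_vector(phenotype, probs.individual_ids)
    keep = np.isfinite(y)
    y = y[keep]
    scanner = _FastScanner(probs, keep)
    rng = np.random.default_rng(config.seed)
    maxima = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        maxima[i] = scanner.max_lod(rng.permutation(y))
    threshold = float(np.quantile(maxima, 1.0 - config.alpha, method="higher"))
    if return_maxima:
        return threshold, maxima
    return threshold


def null_scan_calibration(
    probs: GenotypeProbabilities,
    n_replicates: int = 200,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical genome-wide type-I error of the permutation threshold.

    Draws ``n_replicates`` independent Gaussian null phenotypes on the given
    genotypes; for each, computes its own permutation threshold (at
    ``n_permutations`` and level ``alpha``) and records whether the
    replicate's real maximum LOD exceeds it. Returns the exceedance rate,
    which should be close to ``alpha`` for a calibrated threshold.
    """
    rng = np.random.default_rng(seed)
    n = len(probs.individual_ids)
    scanner = _FastScanner(probs, np.ones(n, dtype=bool))
    exceed = 0
    for _ in range(n_replicates):
        y = rng.normal(size=n)
        maxima = np.empty(n_permutations)
        for i in range(n_permutations):
            maxima[i] = scanner.max_lod(rng.permutation(y))
        threshold = np.quantile(maxima, 1.0 - alpha, method="higher")
        if scanner.max_lod(y) > threshold:
            exceed += 1
    return exceed / n_replicates


# ---------------------------------------------------------------------------
# support intervals and reporting


def support_interval(
    scan: ScanResult,
    gmap: GeneticMap,
    lod_drop: float = 2.0,
    peak_index: int | None = None,
) -> SupportInterval:
    """LOD-drop support interval around a peak, bracketed by flanking markers.

    The interval is the contiguous grid region around the peak with
    LOD >= peak - lod_drop, restricted to the peak's chromosome. The
    reported markers are the nearest markers at or outside the region's
    ends; at a chromosome edge the interval is one-sided.
    """
    if peak_index is None:
        peak_index = scan.peak()
    peak_lod = scan.lod[peak_index]
    if not np.isfinite(peak_lod):
        raise ValueError("scan peak is not finite")
    chrom = scan.chrom[peak_index]
    on_chrom = np.flatnonzero(scan.chrom == chrom)
    lo = hi = peak_index
    floor = peak_lod - lod_drop
    while lo - 1 in on_chrom and scan.lod[lo - 1] >= floor:
        lo -= 1
    while hi + 1 in on_chrom and scan.lod[hi + 1] >= floor:
        hi += 1
    left_cm = float(scan.cm[lo])
    right_cm = float(scan.cm[hi])

    markers = gmap.chrom_markers(chrom)
    mcm = markers["cm"].to_numpy(float)
    ids = markers["marker_id"].to_list()
    at_or_left = np.flatnonzero(mcm <= left_cm + 1e-9)
    at_or_right = np.flatnonzero(mcm >= right_cm - 1e-9)
    left_marker = ids[at_or_left[-1]] if len(at_or_left) else ids[0]
    right_marker = ids[at_or_right[0]] if len(at_or_right) else ids[-1]
    return SupportInterval(chrom, left_cm, right_cm, left_marker, right_marker)


def lod_to_r2(lod: float, n: int) -> float:
    """Percent variance explained implied by a LOD score at sample size n."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


def _chrom_label(chrom) -> str:
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


def _find_peaks(scan: ScanResult, threshold: float) -> list[int]:
    """One peak index per contiguous supra-threshold segment, per chromosome."""
    peaks = []
    above = scan.lod > threshold
    start = None
    for i in range(len(above) + 1):
        boundary = (
            i == len(above)
            or not above[i]
            or (i > 0 and scan.chrom[i] != scan.chrom[i - 1])
        )
        if start is not None and boundary:
            seg = slice(start, i)
            peaks.append(start + int(np.argmax(scan.lod[seg])))
            start = None
        if i < len(above) and above[i] and start is None:
            start = i
    return peaks


def report_qtls(
    scans: Mapping[str, ScanResult],
    threshold,
    gmap: GeneticMap,
    lod_drop: float = 2.0,
    merge_cm: float = 15.0,
) -> list[QTLReport]:
    """Collate supra-threshold peaks from one or more experiments into QTLs.

    Peaks from different experiments on the same chromosome are treated as
    the same locus when their peaks lie within ``merge_cm`` or their support
    intervals overlap; such loci are flagged as repeatedly detected. Loci are
    named ``qLTT{chrom}.{index}`` in positional order along each chromosome.

    ``threshold`` may be a single LOD value or a mapping experiment -> value.
    """
    entries = []  # (chrom, peak_cm, experiment, report-less data)
    for exp, scan in scans.items():
        thr = threshold[exp] if isinstance(threshold, Mapping) else float(threshold)
        for idx in _find_peaks(scan, thr):
            interval = support_interval(scan, gmap, lod_drop, peak_index=idx)
            entries.append(
                {
                    "experiment": exp,
                    "chrom": scan.chrom[idx],
                    "peak_cm": float(scan.cm[idx]),
                    "peak_lod": float(scan.lod[idx]),
                    "interval": interval,
                    "r2_pct": float(scan.r2[idx]),
                }
            )
    if not entries:
        return []

    # cluster entries into loci per chromosome
    loci: list[list[dict]] = []
    for e in sorted(entries, key=lambda e: (str(e["chrom"]), e["peak_cm"])):
        placed = False
        for locus in loci:
            ref = locus[0]
            if ref["chrom"] != e["chrom"]:
                continue
            close = abs(ref["peak_cm"] - e["peak_cm"]) <= merge_cm
            overlap = (
                e["interval"].left_cm <= ref["interval"].right_cm
                and ref["interval"].left_cm <= e["interval"].right_cm
            )
            if close or overlap:
                locus.append(e)
                placed = True
                break
        if not placed:
            loci.append([e])

    # positional naming per chromosome
    loci.sort(key=lambda locus: (str(locus[0]["chrom"]), min(x["peak_cm"] for x in locus)))
    index_on_chrom: dict = {}
    reports = []
    for locus in loci:
        chrom = locus[0]["chrom"]
        index_on_chrom[chrom] = index_on_chrom.get(chrom, 0) + 1
        name = f"qLTT{_chrom_label(chrom)}.{index_on_chrom[chrom]}"
        repeated = len({e["experiment"] for e in locus}) > 1
        for e in locus:
            reports.append(
                QTLReport(
                    name=name,
                    experiment=e["experiment"],
                    chrom=chrom,
                    peak_cm=e["peak_cm"],
                    peak_lod=e["peak_lod"],
                    interval=e["interval"],
                    r2_pct=e["r2_pct"],
                    repeatedly_detected=repeated,
                )
            )
    return reports


def qtl_report_frame(reports: Iterable[QTLReport]) -> pd.DataFrame:
    """QTL report as a table with the usual columns."""
    rows = []
    for r in reports:
        rows.append(
            {
                "qtl": r.name,
                "experiment": r.experiment,
                "chrom": r.chrom,
                "peak_cm": round(r.peak_cm, 1),
                "peak_lod": round(r.peak_lod, 1),
                "interval": (
                    f"{r.interval.left_marker}({r.interval.left_cm:.1f})-"
                    f"{r.interval.right_marker}({r.interval.right_cm:.1f})"
                ),
                "r2_pct": round(r.r2_pct, 1),
                "repeatedly_detected": r.repeatedly_detected,
            }
        )
    return pd.DataFrame(rows)
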
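"""Ground-truthed negative-binomial scRNA-seq simulator.

The generator emulates a droplet scRNA-seq experiment on a degenerating
retina: several discrete cell populations across two genotypes, one
population (the rods) strung along a continuous degeneration trajectory,
genes following four pseudotemporal pattern classes, per-cell size factors,
mitochondrial transcripts, plus injected doublets and damaged low-quality
cells. Every cell and gene carries its ground-truth label so downstream
stages can be scored exactly.

Counts are NB(mean = s_c * b_g * f_g(t_c), dispersion = theta) with
variance mu + mu^2/theta, sampled as a gamma-Poisson mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

PATTERN_CLASSES = ("down", "early_permanent_up", "early_transient_up", "late_up")

#: Protein-coding mouse mitochondrial gene symbols (13 genes).
MITO_SYMBOLS = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


class SyntheticSpecError(ValueError):
    """Invalid simulation specification; the message names the field."""


@dataclass(frozen=True)
class Population:
    """``identity`` groups populations of one cell type (e.g. wild-type and
    mutant cones) so they share the same baseline expression program; it
    defaults to the population name."""

    name: str
    n_cells: int
    genotype: str = "wt"
    identity: str | None = None

    @property
    def cell_type(self) -> str:
        return self.identity if self.identity is not None else self.name


def _logistic(t: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(t, dtype=float) - midpoint)))


def pattern_mean_function(pattern_class: str, effect_size: float):
    """Multiplicative trajectory factor f(t) for one pattern class.

    ``effect_size`` is the maximum |log2 fold change| reached over t in [0,1].
    Shapes: "down" is a decreasing sigmoid, "early_permanent_up" rises early
    and stays up (midpoint 0.35), "early_transient_up" is a Gaussian bump
    centered at t=0.4 returning to baseline, "late_up" rises late
    (midpoint 0.75).
    """
    d = float(effect_size)
    if pattern_class == "down":
        return lambda t: 2.0 ** (-d * _logistic(t, 0.5, 10.0))
    if pattern_class == "early_permanent_up":
        return lambda t: 2.0 ** (d * _logistic(t, 0.35, 12.0))
    if pattern_class == "early_transient_up":
        return lambda t: 2.0 ** (d * np.exp(-((np.asarray(t, float) - 0.4) ** 2) / (2 * 0.13**2)))
    if pattern_class == "late_up":
        return lambda t: 2.0 ** (d * _logistic(t, 0.75, 14.0))
    raise SyntheticSpecError(f"pattern_genes: unknown pattern class {pattern_class!r}")


@dataclass
class SyntheticSpec:
    """Parameters of one simulated experiment; defaults give the standard
    desk-scale validation scenario (five populations, ~3800 cells, 2000 genes).
    """

    populations: list[Population] = field(default_factory=lambda: [
        Population("rod", 2400, "rd10"),
        Population("cone_wt", 250, "wt", identity="cone"),
        Population("cone_rd10", 250, "rd10", identity="cone"),
        Population("mueller", 400, "wt"),
        Population("bipolar", 300, "wt"),
    ])
    trajectory_population: str = "rod"
    # pseudotime is a 3-stage mixture of truncated normals on [0,1]
    stage_centers: tuple = (0.12, 0.50, 0.88)
    stage_sd: float = 0.07
    stage_weights: tuple = (0.34, 0.33, 0.33)
    stage_names: tuple = ("wt", "early", "late")
    stage_genotypes: tuple = ("wt", "rd10", "rd10")
    pattern_genes: dict = field(default_factory=lambda: {c: 50 for c in PATTERN_CLASSES})
    effect_size: float = 2.0  # max |log2 FC| along the trajectory
    n_background_genes: int = 1687
    marker_genes_per_population: int = 20
    marker_fold: float = 100.0
    marker_base_mean: float = 0.03
    pattern_base_range: tuple = (0.25, 1.0)
    background_base_log_mean: float = float(np.log(0.5))
    background_base_log_sigma: float = 1.2
    mito_base_mean: float = 8.0
    # per-cell-type baseline modulation of background/pattern genes (log-sd);
    # distinguishes cell types beyond their specific markers
    identity_sigma: float = 0.4
    nb_dispersion: float = 2.0
    size_factor_lognormal_sigma: float = 0.3
    mito_gene_count: int = 13
    doublet_rate: float = 0.0
    lowq_rate: float = 0.0
    lowq_factor_range: tuple = (0.05, 0.2)
    doublet_depth_factor: float = 1.3
    # optional coupling: a non-trajectory population partially adopts the
    # pattern-gene program at a fixed trajectory position (e.g. mutant cones
    # echoing the late-degeneration rod program)
    coupled_population: str | None = None
    coupling_strength: float = 0.9
    coupling_pseudotime: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise SyntheticSpecError("populations: must be nonempty")
        for p in self.populations:
            if p.n_cells < 0:
                raise SyntheticSpecError(f"populations[{p.name}].n_cells: must be >= 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("populations: names must be unique")
        if self.trajectory_population not in names:
            raise SyntheticSpecError(
                f"trajectory_population: {self.trajectory_population!r} not among populations"
            )
        for cls, n in self.pattern_genes.items():
            if cls not in PATTERN_CLASSES:
                raise SyntheticSpecError(f"pattern_genes: unknown class {cls!r}")
            if n < 0:
                raise SyntheticSpecError(f"pattern_genes[{cls}]: must be >= 0")
        if self.n_background_genes < 0:
            raise SyntheticSpecError("n_background_genes: must be >= 0")
        if self.marker_genes_per_population < 0:
            raise SyntheticSpecError("marker_genes_per_population: must be >= 0")
        if self.nb_dispersion <= 0:
            raise SyntheticSpecError("nb_dispersion: must be > 0")
        if self.size_factor_lognormal_sigma < 0:
            raise SyntheticSpecError("size_factor_lognormal_sigma: must be >= 0")
        if self.mito_gene_count < 0 or self.mito_gene_count > len(MITO_SYMBOLS):
            raise SyntheticSpecError(
                f"mito_gene_count: must be in [0, {len(MITO_SYMBOLS)}]"
            )
        if not (0 <= self.doublet_rate < 0.5):
            raise SyntheticSpecError("doublet_rate: must be in [0, 0.5)")
        if self.lowq_rate < 0:
            raise SyntheticSpecError("lowq_rate: must be >= 0")
        if self.doublet_rate + self.lowq_rate >= 1:
            raise SyntheticSpecError("doublet_rate + lowq_rate: must be < 1")
        if self.coupled_population is not None and self.coupled_population not in names:
            raise SyntheticSpecError(
                f"coupled_population: {self.coupled_population!r} not among populations"
            )


@dataclass
class SyntheticDataset:
    """Counts plus per-cell (``cells``) and per-gene (``genes``) ground truth.

    ``cells`` columns: population, stage, genotype, pseudotime (NaN outside the
    trajectory population), doublet, lowq. ``genes`` columns: pattern
    ("background", "mito", "marker:<pop>" or one of the four pattern classes),
    base_mean, expected_mean (theoretical per-gene mean over simulated cells).
    """

    counts: CountMatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    spec: SyntheticSpec

    @property
    def truth_population(self) -> np.ndarray:
        return self.cells["population"].to_numpy()

    @property
    def truth_stage(self) -> np.ndarray:
        return self.cells["stage"].to_numpy()

    @property
    def truth_pseudotime(self) -> np.ndarray:
        return self.cells["pseudotime"].to_numpy()

    @property
    def truth_pattern(self) -> np.ndarray:
        return self.genes["pattern"].to_numpy()

    @property
    def truth_doublet(self) -> np.ndarray:
        return self.cells["doublet"].to_numpy()

    @property
    def truth_lowq(self) -> np.ndarray:
        return self.cells["lowq"].to_numpy()


def _build_gene_table(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sym in MITO_SYMBOLS[: spec.mito_gene_count]:
        rows.append((sym, "mito", spec.mito_base_mean))
    for pop in spec.populations:
        for i in range(spec.marker_genes_per_population):
            rows.append((f"Mk-{pop.name}-{i + 1}", f"marker:{pop.name}", spec.marker_base_mean))
    lo, hi = spec.pattern_base_range
    for cls in PATTERN_CLASSES:
        n = spec.pattern_genes.get(cls, 0)
        bases = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        for i in range(n):
            rows.append((f"Pat-{cls}-{i + 1}", cls, bases[i]))
    bg = np.exp(
        rng.normal(spec.background_base_log_mean, spec.background_base_log_sigma,
                   size=spec.n_background_genes)
    )
    bg = np.clip(bg, 0.01, 20.0)
    for i in range(spec.n_background_genes):
        rows.append((f"Bg-{i + 1}", "background", bg[i]))
    genes = pd.DataFrame(rows, columns=["symbol", "pattern", "base_mean"])
    genes["id"] = ["g%05d" % (i + 1) for i in range(len(genes))]
    return genes


def _sample_stage_pseudotime(spec: SyntheticSpec, n: int, rng: np.random.Generator):
    stage = rng.choice(len(spec.stage_centers), size=n, p=np.asarray(spec.stage_weights))
    t = rng.normal(np.asarray(spec.stage_centers)[stage], spec.stage_sd)
    # reflect into [0,1] (truncation by reflection keeps the mixture shape)
    t = np.abs(t)
    t = 1.0 - np.abs(1.0 - t)
    return np.clip(t, 0.0, 1.0), stage


def _mean_matrix(spec: SyntheticSpec, genes: pd.DataFrame, cells: pd.DataFrame,
                 size_factors: np.ndarray,
                 identity_factors: dict[str, np.ndarray] | None = None) -> np.ndarray:
    n_genes, n_cells = len(genes), len(cells)
    factor = np.ones((n_genes, n_cells))
    pop = cells["population"].to_numpy()
    pattern = genes["pattern"].to_numpy()
    # population marker enrichment and shared cell-type baseline programs
    for p in spec.populations:
        gmask = pattern == f"marker:{p.name}"
        cmask = pop == p.name
        if gmask.any() and cmask.any():
            factor[np.ix_(gmask, cmask)] *= spec.marker_fold
        if identity_factors is not None and cmask.any():
            factor[:, cmask] *= identity_factors[p.cell_type][:, None]
    # trajectory pattern programs
    traj = pop == spec.trajectory_population
    t = cells["pseudotime"].to_numpy()
    for cls in PATTERN_CLASSES:
        gmask = pattern == cls
        if not gmask.any():
            continue
        f = pattern_mean_function(cls, spec.effect_size)
        if traj.any():
            factor[np.ix_(gmask, traj)] *= f(t[traj])[None, :]
        if spec.coupled_population is not None:
            cmask = pop == spec.coupled_population
            if cmask.any():
                val = float(f(spec.coupling_pseudotime)) ** spec.coupling_strength
                factor[np.ix_(gmask, cmask)] *= val
    base = genes["base_mean"].to_numpy()[:, None]
    return base * factor * size_factors[None, :]


def simulate_counts(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate singlet cells per the spec; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _build_gene_table(spec, rng)
    # shared baseline program per cell type on background and pattern genes
    modifiable = genes["pattern"].isin(list(PATTERN_CLASSES) + ["background"]).to_numpy()
    identity_factors = {}
    for ct in dict.fromkeys(p.cell_type for p in spec.populations):
        f = np.ones(len(genes))
        f[modifiable] = np.exp(rng.normal(0.0, spec.identity_sigma, size=modifiable.sum()))
        identity_factors[ct] = f

    cell_rows = []
    for p in spec.populations:
        if p.name == spec.trajectory_population:
            t, stage_idx = _sample_stage_pseudotime(spec, p.n_cells, rng)
            for j in range(p.n_cells):
                s = stage_idx[j]
                cell_rows.append((
                    p.name, f"{p.name}/{spec.stage_names[s]}",
                    spec.stage_genotypes[s], t[j],
                ))
        else:
            for _ in range(p.n_cells):
                cell_rows.append((p.name, p.name, p.genotype, np.nan))
    cells = pd.DataFrame(cell_rows, columns=["population", "stage", "genotype", "pseudotime"])
    cells["doublet"] = False
    cells["lowq"] = False
    order = rng.permutation(len(cells))
    cells = cells.iloc[order].reset_index(drop=True)
    cells["barcode"] = ["cell-%05d" % (i + 1) for i in range(len(cells))]

    sf = np.exp(rng.normal(0.0, spec.size_factor_lognormal_sigma, size=len(cells)))
    sf /= sf.mean() if len(sf) else 1.0
    mu = _mean_matrix(spec, genes, cells, sf, identity_factors)
    theta = spec.nb_dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    genes = genes.copy()
    genes["expected_mean"] = mu.mean(axis=1) if len(cells) else 0.0
    cm = CountMatrix(
        sp.csr_matrix(counts),
        genes[["id", "symbol"]].reset_index(drop=True),
        cells["barcode"].to_numpy(),
    )
    return SyntheticDataset(cm, cells, genes, spec)


def inject_artifacts(dataset: SyntheticDataset, spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Append doublets and low-quality cells per the spec's rates.

    Doublets are element-wise sums of two random cells from *different*
    populations, binomially thinned to ``doublet_depth_factor`` times the
    median singlet depth. Low-quality cells are copies of random singlets with
    non-mitochondrial counts thinned by a factor drawn from
    ``lowq_factor_range`` while mitochondrial counts are preserved, which
    raises the mitochondrial fraction — the signature of a damaged cell.
    """
    spec = dataset.spec if spec is None else spec
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA27)))
    X = dataset.counts.matrix.toarray()
    n = X.shape[1]
    pops = dataset.cells["population"].to_numpy()
    n_doublets = int(round(spec.doublet_rate * n))
    n_lowq = int(round(spec.lowq_rate * n))
    if n_doublets > 0 and len(np.unique(pops)) < 2:
        raise SyntheticSpecError("doublet_rate: doublet pairing impossible with a single population")

    new_cols, new_rows = [], []
    median_depth = np.median(X.sum(axis=0)) if n else 0.0
    target = spec.doublet_depth_factor * median_depth
    for d in range(n_doublets):
        while True:
            i, j = rng.integers(0, n, size=2)
            if pops[i] != pops[j]:
                break
        col = X[:, i] + X[:, j]
        tot = col.sum()
        if tot > target > 0:
            col = rng.binomial(col, target / tot)
        new_cols.append(col)
        new_rows.append({
            "population": "doublet", "stage": "doublet", "genotype": "mixed",
            "pseudotime": np.nan, "doublet": True, "lowq": False,
            "barcode": "dbl-%05d" % (d + 1),
        })

    mito = dataset.genes["pattern"].to_numpy() == "mito"
    lo, hi = spec.lowq_factor_range
    for q in range(n_lowq):
        i = int(rng.integers(0, n))
        f = float(rng.uniform(lo, hi))
        col = X[:, i].copy()
        col[~mito] = rng.binomial(col[~mito], f)
        new_cols.append(col)
        new_rows.append({
            "population": pops[i], "stage": "lowq", "genotype": dataset.cells["genotype"].iloc[i],
            "pseudotime": np.nan, "doublet": False, "lowq": True,
            "barcode": "lowq-%05d" % (q + 1),
        })

    if not new_cols:
        return dataset
    Xfull = np.column_stack([X] + [np.asarray(c) for c in new_cols])
    cells = pd.concat([dataset.cells, pd.DataFrame(new_rows)], ignore_index=True)
    cm = CountMatrix(sp.csr_matrix(Xfull), dataset.counts.features, cells["barcode"].to_numpy())
    return SyntheticDataset(cm, cells, dataset.genes, spec)


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Convenience: simulate singlets, then inject doublets/low-quality cells."""
    return inject_artifacts(simulate_counts(spec), spec)
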
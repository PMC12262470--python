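"""Synthetic kidney scRNA-seq data and drug-target databases.

Generates annotated cell-by-gene count matrices with a two-level cell-type
hierarchy (4 abstract parent types partitioned into up to 32 detailed
subtypes), multi-donor replicate structure, and negative-binomial counts with
dropout calibrated to a target sparsity.  Also generates drug->target->
nephrotoxicity databases in which the toxicity label can be coupled, with
controllable strength, to marker genes of designated "susceptible" cell
types — the knob that makes downstream signature recovery testable.

The default cell-type composition follows the observed kidney proportions:
Nephron 82.4%, Endothelium 7.8%, Immune 7.1%, Stroma 2.6%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger("nephrosig")

__all__ = [
    "CellTypeSpec",
    "SyntheticConfig",
    "DrugRecord",
    "DrugTargetDB",
    "SignalSpec",
    "gene_universe",
    "abstract_cell_type_specs",
    "detailed_cell_type_specs",
    "default_config",
    "generate_cell_matrix",
    "generate_drug_db",
    "generate_bulk_profiles",
    "ABSTRACT_PREVALENCES",
    "DETAILED_SUBTYPES",
]

# ---------------------------------------------------------------------------
# Cell-type hierarchy
# ---------------------------------------------------------------------------

ABSTRACT_TYPES = ("Nephron", "Endothelium", "Immune", "Stroma")

#: Abstract kidney cell-type prevalences (fractions of all cells).
ABSTRACT_PREVALENCES = {
    "Nephron": 0.824,
    "Endothelium": 0.078,
    "Immune": 0.071,
    "Stroma": 0.026,
}

#: Detailed subtypes per abstract parent (32 total), kidney-atlas style names.
DETAILED_SUBTYPES = {
    "Nephron": [
        "Proximal tubule",
        "Distinct proximal tubule 1",
        "Distinct proximal tubule 2",
        "Proliferating Proximal Tubule",
        "Indistinct intercalated cell",
        "Type A intercalated cell",
        "Type B intercalated cell",
        "Principal cell",
        "Connecting tubule",
        "Distal convoluted tubule",
        "Thick ascending limb of Loop of Henle",
        "Descending thin limb",
        "Ascending thin limb",
        "Podocyte",
        "Parietal epithelial cell",
        "Epithelial progenitor cell",
        "Pelvic epithelium",
        "Transitional urothelium",
        "Macula densa",
        "Proliferating distal tubule",
    ],
    "Endothelium": [
        "Peritubular capillary endothelium 1",
        "Peritubular capillary endothelium 2",
        "Glomerular endothelium",
        "Ascending vasa recta endothelium",
        "Descending vasa recta endothelium",
    ],
    "Immune": [
        "MNP-a/classical monocyte derived",
        "MNP-b/non-classical monocyte derived",
        "CD4 T cell",
        "CD8 T cell",
        "NK cell",
    ],
    "Stroma": [
        "Fibroblast",
        "Myofibroblast",
    ],
}


@dataclass(frozen=True)
class CellTypeSpec:
    """Expression model of one (detailed or abstract) cell type.

    ``base_mean`` holds the expected NB count per gene in cells of this type;
    ``dispersion`` the per-gene NB shape parameter r (var = mu + mu^2/r).
    ``marker_genes`` are, by construction, the top-expressed genes of the
    type and the pool that signal-carrying drugs draw their targets from.
    """

    name: str
    abstract_parent: str
    prevalence: float
    marker_genes: frozenset[str]
    base_mean: np.ndarray
    dispersion: np.ndarray

    def __post_init__(self) -> None:
        if self.abstract_parent not in ABSTRACT_TYPES:
            raise ValueError(
                f"abstract_parent {self.abstract_parent!r} not one of {ABSTRACT_TYPES}"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if np.any(np.asarray(self.base_mean) < 0):
            raise ValueError("base_mean must be nonnegative")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be positive")


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic dataset; ``seed`` determines everything."""

    n_cells: int
    n_genes: int
    n_donors: int
    target_sparsity: float
    seed: int
    cell_type_specs: list[CellTypeSpec]
    donor_sigma: float = 0.3  # sd of the per-(donor, gene) lognormal factor

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2 (replicates needed for t-tests)")
        if not 0.0 <= self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must be in [0, 1)")
        if self.n_cells < len(self.cell_type_specs):
            raise ValueError("too few cells for the number of cell types")
        total = sum(s.prevalence for s in self.cell_type_specs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type prevalences sum to {total}, expected 1")
        genes = set(gene_universe(self.n_genes))
        for s in self.cell_type_specs:
            if len(s.base_mean) != self.n_genes or len(s.dispersion) != self.n_genes:
                raise ValueError(f"spec {s.name!r} mean/dispersion length != n_genes")
            if not set(s.marker_genes) <= genes:
                raise ValueError(f"markers of {s.name!r} outside the gene universe")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    target_genes: frozenset[str]
    nephrotoxic: bool

    def __post_init__(self) -> None:
        if not self.target_genes:
            raise ValueError(f"drug {self.drug_id!r} has no target genes")


@dataclass
class DrugTargetDB:
    """A set of drugs with target-gene annotations and binary toxicity labels."""

    records: list[DrugRecord]

    def __post_init__(self) -> None:
        ids = [r.drug_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate drug_id in database")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_toxic(self) -> int:
        return sum(r.nephrotoxic for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": [r.drug_id for r in self.records],
                "target_genes": [";".join(sorted(r.target_genes)) for r in self.records],
                "nephrotoxic": [int(r.nephrotoxic) for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugTargetDB":
        records = [
            DrugRecord(
                drug_id=str(row.drug_id),
                target_genes=frozenset(str(row.target_genes).split(";")),
                nephrotoxic=bool(int(row.nephrotoxic)),
            )
            for row in df.itertuples()
        ]
        return cls(records)


@dataclass(frozen=True)
class SignalSpec:
    """Coupling between toxicity labels and susceptible-cell-type markers.

    ``enrichment_strength`` is the fraction of each nephrotoxic drug's targets
    drawn from marker genes of the susceptible types; 0 yields a null database
    in which labels carry no information about targets.
    """

    susceptible_cell_types: frozenset[str] = frozenset()
    enrichment_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ValueError("enrichment_strength must be in [0, 1]")


# ---------------------------------------------------------------------------
# Default expression models
# ---------------------------------------------------------------------------

def gene_universe(n_genes: int) -> list[str]:
    """Synthetic gene symbols G000001..G<n>."""
    return [f"G{i + 1:06d}" for i in range(n_genes)]


def _baseline_means(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    # Long-tailed gene mean distribution: most genes lowly expressed, as in
    # droplet scRNA-seq after gene filtering.
    return rng.lognormal(mean=np.log(0.08), sigma=1.6, size=n_genes)

def _dispersions(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    return rng.lognormal(mean=np.log(0.35), sigma=0.25, size=n_genes)


def _subtype_weights(k: int) -> np.ndarray:
    # Geometric decay: realistic skew (one dominant subtype per lineage).
    w = 0.8 ** np.arange(k)
    return w / w.sum()


def _build_specs(
    names_parents: list[tuple[str, str]],
    prevalences: np.ndarray,
    n_genes: int,
    marker_fold: float,
    n_markers: int,
    spec_seed: int,
) -> list[CellTypeSpec]:
    rng = np.random.default_rng(spec_seed)
    genes = gene_universe(n_genes)
    base = _baseline_means(n_genes, rng)
    disp = _dispersions(n_genes, rng)
    n_types = len(names_parents)
    n_markers = min(n_markers, max(1, n_genes // (2 * n_types)))

    # disjoint marker blocks at the start of the universe
    marker_idx = [
        np.arange(t * n_markers, (t + 1) * n_markers) for t in range(n_types)
    ]
    all_marker_idx = np.concatenate(marker_idx)

    specs = []
    for t, (name, parent) in enumerate(names_parents):
        mean = base * rng.lognormal(0.0, 0.1, size=n_genes)  # mild type identity
        mean[all_marker_idx] = 0.04  # markers of any type are low elsewhere...
        mean[marker_idx[t]] = marker_fold  # ...and high in their own type
        specs.append(
            CellTypeSpec(
                name=name,
                abstract_parent=parent,
                prevalence=float(prevalences[t]),
                marker_genes=frozenset(genes[i] for i in marker_idx[t]),
                base_mean=mean,
                dispersion=disp.copy(),
            )
        )
    return specs


def abstract_cell_type_specs(
    n_genes: int,
    *,
    marker_fold: float = 4.0,
    n_markers: int = 25,
    spec_seed: int = 0,
) -> list[CellTypeSpec]:
    """Four abstract kidney types at the observed prevalences."""
    names = [(t, t) for t in ABSTRACT_TYPES]
    prev = np.array([ABSTRACT_PREVALENCES[t] for t in ABSTRACT_TYPES])
    prev = prev / prev.sum()  # published fractions sum to 0.999 ("approximately")
    return _build_specs(names, prev, n_genes, marker_fold, n_markers, spec_seed)


def detailed_cell_type_specs(
    n_genes: int,
    *,
    marker_fold: float = 4.0,
    n_markers: int = 25,
    spec_seed: int = 0,
) -> list[CellTypeSpec]:
    """32 detailed subtypes partitioned under the 4 abstract parents.

    Subtype prevalences split each parent's share with geometric decay, so
    every lineage has a dominant subtype and a tail of rare ones.
    """
    names, prev = [], []
    for parent in ABSTRACT_TYPES:
        subs = DETAILED_SUBTYPES[parent]
        w = _subtype_weights(len(subs)) * ABSTRACT_PREVALENCES[parent]
        names.extend((s, parent) for s in subs)
        prev.extend(w)
    prev = np.asarray(prev)
    prev = prev / prev.sum()
    return _build_specs(names, prev, n_genes, marker_fold, n_markers, spec_seed)


def default_config(
    seed: int,
    *,
    n_cells: int = 10_000,
    n_genes: int = 20_000,
    n_donors: int = 24,
    target_sparsity: float = 0.90,
    level: str = "detailed32",
) -> SyntheticConfig:
    """The default study conditions: 10k cells, 20k genes, 24 donors, 90% zeros."""
    builder = detailed_cell_type_specs if level == "detailed32" else abstract_cell_type_specs
    return SyntheticConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        n_donors=n_donors,
        target_sparsity=target_sparsity,
        seed=seed,
        cell_type_specs=builder(n_genes),
    )


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _expected_zero_fraction(config: SyntheticConfig, scale: float) -> float:
    z = 0.0
    for s in config.cell_type_specs:
        mu = scale * s.base_mean
        r = s.dispersion
        z += s.prevalence * float(np.mean((r / (r + mu)) ** r))
    return z


def _calibrate(config: SyntheticConfig) -> tuple[float, float]:
    """Choose (mean scale, dropout prob) so expected zeros hit target_sparsity."""
    target = config.target_sparsity
    z1 = _expected_zero_fraction(config, 1.0)
    if z1 <= target:
        # NB alone not sparse enough: top up with uniform dropout.
        q = (target - z1) / (1.0 - z1) if z1 < 1.0 else 0.0
        return 1.0, q
    # NB too sparse: scale means up until expected zeros reach target.
    lo, hi = 1.0, 1.0
    while _expected_zero_fraction(config, hi) > target and hi < 1e6:
        hi *= 2.0
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if _expected_zero_fraction(config, mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi)), 0.0


def generate_cell_matrix(config: SyntheticConfig) -> AnnData:
    """Simulate an annotated cell-by-gene count matrix.

    Counts are negative binomial per gene and cell type, modulated by a
    per-(donor, gene) lognormal factor, with multiplicative dropout so the
    realized zero fraction lands within a few points of
    ``config.target_sparsity``.  The same seed always yields the same matrix.

    Returns an :class:`~anndata.AnnData` with raw counts in ``X`` and
    ``obs`` columns ``detailed_type``, ``abstract_type``, ``donor``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = config.cell_type_specs
    n_cells, n_genes = config.n_cells, config.n_genes

    prevalences = np.array([s.prevalence for s in specs])
    counts_per_type = rng.multinomial(n_cells, prevalences)
    scale, dropout = _calibrate(config)

    donor_ids = np.array([f"D{d + 1:02d}" for d in range(config.n_donors)])
    sig = config.donor_sigma
    donor_factor = rng.lognormal(-0.5 * sig**2, sig, size=(config.n_donors, n_genes))

    blocks, det, donors = [], [], []
    chunk = max(1, int(2e7 // n_genes))  # cap dense scratch at ~20M entries
    for s, n_t in zip(specs, counts_per_type):
        if n_t == 0:
            continue
        d_idx = rng.integers(0, config.n_donors, size=n_t)
        mu_type = scale * s.base_mean
        r = s.dispersion
        for start in range(0, n_t, chunk):
            d_chunk = d_idx[start : start + chunk]
            mu = mu_type[None, :] * donor_factor[d_chunk]
            block = rng.negative_binomial(r[None, :], r[None, :] / (r[None, :] + mu))
            if dropout > 0:
                block[rng.random(block.shape) < dropout] = 0
            blocks.append(sp.csr_matrix(block.astype(np.int32)))
        det.extend([s.name] * n_t)
        donors.extend(donor_ids[d_idx])

    X = sp.vstack(blocks, format="csr")
    parent = {s.name: s.abstract_parent for s in specs}
    obs = pd.DataFrame(
        {
            "detailed_type": pd.Categorical(det),
            "abstract_type": pd.Categorical([parent[t] for t in det]),
            "donor": pd.Categorical(donors),
        },
        index=[f"CELL{i + 1:06d}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(index=pd.Index(gene_universe(n_genes), name="gene"))
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["layer"] = "counts"
    realized = 1.0 - X.nnz / (X.shape[0] * X.shape[1])
    adata.uns["zero_fraction"] = realized
    logger.info(
        "simulate: %d cells x %d genes, %d donors, zero fraction %.3f",
        X.shape[0], X.shape[1], config.n_donors, realized,
    )
    return adata


# ---------------------------------------------------------------------------
# Drug database generation
# ---------------------------------------------------------------------------

def generate_drug_db(
    n_toxic: int,
    n_nontoxic: int,
    signal: SignalSpec,
    gene_universe: list[str] | set[str],
    seed: int,
    *,
    cell_type_specs: list[CellTypeSpec] | None = None,
    mean_targets: float = 5.0,
) -> DrugTargetDB:
    """Simulate a drug->target->toxicity database.

    Each nephrotoxic drug draws ``signal.enrichment_strength`` of its targets
    from the pooled marker genes of the susceptible cell types and the rest
    uniformly from the universe; non-nephrotoxic drugs draw all targets
    uniformly.  Target-set sizes are 1 + Poisson(mean_targets - 1).
    """
    if n_toxic <= 0 or n_nontoxic <= 0:
        raise ValueError("drug counts must be positive")
    universe = sorted(set(gene_universe))
    if not universe:
        raise ValueError("gene universe is empty")

    markers: list[str] = []
    if signal.enrichment_strength > 0:
        if cell_type_specs is None:
            raise ValueError("cell_type_specs required when enrichment_strength > 0")
        pool: set[str] = set()
        for s in cell_type_specs:
            if s.name in signal.susceptible_cell_types:
                pool |= set(s.marker_genes)
        markers = sorted(pool & set(universe))
        if not markers:
            raise ValueError(
                "susceptible cell types contribute no marker genes in the universe"
            )

    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    mk = np.array(markers) if markers else None
    records = []
    for i in range(n_toxic + n_nontoxic):
        toxic = i < n_toxic
        k = 1 + rng.poisson(max(mean_targets - 1.0, 0.0))
        if toxic and signal.enrichment_strength > 0:
            k_m = int(round(signal.enrichment_strength * k))
            k_u = k - k_m  # fixed before capping: enrichment 1 never backfills
            k_m = min(k_m, len(mk))
            chosen = set(rng.choice(mk, size=max(k_m, 1), replace=False))
        else:
            chosen, k_u = set(), k
        if k_u > 0:
            chosen |= set(rng.choice(uni, size=min(k_u, len(uni)), replace=False))
        records.append(
            DrugRecord(
                drug_id=f"DRUG{i + 1:04d}",
                target_genes=frozenset(chosen),
                nephrotoxic=toxic,
            )
        )
    return DrugTargetDB(records)


# ---------------------------------------------------------------------------
# Synthetic bulk signatures (LINCS-like replicate structure)
# ---------------------------------------------------------------------------

def generate_bulk_profiles(
    db: DrugTargetDB,
    n_genes: int,
    seed: int,
    *,
    n_replicates: int = 3,
    n_signal_genes: int = 0,
    effect: float = 0.0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate z-score-like bulk signatures with per-drug replicates.

    Returns ``(profiles, meta)``: profiles is samples x genes, meta carries
    ``drug_id`` and ``nephrotoxic`` per sample.  With ``effect > 0`` the first
    ``n_signal_genes`` genes are shifted by ``effect`` in toxic-drug samples.
    """
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    rows, meta_rows = [], []
    for rec in db.records:
        base = rng.normal(0.0, 0.5, size=n_genes)
        if rec.nephrotoxic and n_signal_genes > 0:
            base[:n_signal_genes] += effect
        for r in range(n_replicates):
            rows.append(base + rng.normal(0.0, noise_sd, size=n_genes))
            meta_rows.append((f"{rec.drug_id}_rep{r + 1}", rec.drug_id, rec.nephrotoxic))
    profiles = pd.DataFrame(
        np.asarray(rows), columns=genes, index=[m[0] for m in meta_rows]
    )
    meta = pd.DataFrame(
        {
            "drug_id": [m[1] for m in meta_rows],
            "nephrotoxic": [bool(m[2]) for m in meta_rows],
        },
        index=profiles.index,
    )
    return profiles, meta
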
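"""Synthetic scRNA-seq cohorts with planted clonal copy-number events.

The generator emulates the structure the downstream analysis assumes: a
diploid "reference" population (normal melanocytes), tumor clones carrying
arm-level copy-number events whose expression follows a dosage law, a
planted "active" subpopulation over-expressing activity gene sets,
negative-binomial count noise with per-cell library sizes and mitochondrial
fractions, and gene-wise multiplicative batch effects.

Model
-----
Per-gene baseline means are drawn LogNormal(0, ``baseline_logmean_sd``) and
normalised to sum to 1, so a cell's expected library size equals its drawn
``L_i``. The expected count of gene g in cell i of clone c is

    lambda_ig = L_i * mu_g * (cn_{g,c} / 2)**alpha * b_{batch(i),g}

with counts ~ NegativeBinomial(mean lambda_ig, dispersion theta), sampled
as a Gamma–Poisson mixture. Active cells additionally multiply the genes of
every activity set by ``activity_fold``. Mitochondrial genes are re-scaled
per cell so that the expected mitochondrial fraction equals a per-cell draw
from ``mito_pct_range``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CloneSpec",
    "BatchSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_gene_annotation",
    "simulate_counts",
    "default_config",
]


@dataclass
class CloneSpec:
    """A tumor clone: size, arm-level copy numbers, and active fraction.

    ``arm_events`` maps arm ids like ``"1q"`` to integer copy numbers in
    [0, 6]; arms not listed are diploid (copy number 2).
    """

    name: str
    n_cells: int
    arm_events: dict[str, int] = field(default_factory=dict)
    active_fraction: float = 0.0


@dataclass
class BatchSpec:
    """A technical batch: fraction of all cells and effect magnitude.

    ``effect_sd`` is the SD of the gene-wise LogNormal multiplicative
    factor; 0 means the batch leaves expression untouched.
    """

    name: str
    cell_fraction: float
    effect_sd: float = 0.0


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    genes_per_arm: int = 60
    n_reference_cells: int = 400
    clones: list[CloneSpec] = field(default_factory=list)
    dosage_exponent: float = 1.0
    baseline_logmean_sd: float = 1.0
    nb_dispersion: float = 2.0
    mean_library_size: float = 5000.0
    library_size_logsd: float = 0.25
    mito_gene_fraction: float = 0.03
    mito_pct_range: tuple[float, float] = (1.0, 8.0)
    batches: list[BatchSpec] = field(default_factory=lambda: [BatchSpec("batch1", 1.0)])
    activity_gene_sets: dict[str, int] = field(default_factory=dict)
    activity_fold: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_arm < 1:
            raise ValueError("n_chromosomes and genes_per_arm must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.dosage_exponent < 0:
            raise ValueError("dosage_exponent must be >= 0")
        if not self.batches:
            raise ValueError("at least one batch is required")
        total = sum(b.cell_fraction for b in self.batches)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"batch cell fractions sum to {total}, expected 1")
        for clone in self.clones:
            for arm, cn in clone.arm_events.items():
                if not (isinstance(cn, (int, np.integer)) and 0 <= cn <= 6):
                    raise ValueError(
                        f"clone {clone.name!r}: copy number for {arm} must be an "
                        f"integer in [0, 6], got {cn!r}"
                    )
            if not 0.0 <= clone.active_fraction <= 1.0:
                raise ValueError(f"clone {clone.name!r}: active_fraction outside [0, 1]")
        if not 0.0 <= self.mito_gene_fraction < 1.0:
            raise ValueError("mito_gene_fraction must be in [0, 1)")
        lo, hi = self.mito_pct_range
        if not 0.0 <= lo <= hi < 100.0:
            raise ValueError("mito_pct_range must satisfy 0 <= lo <= hi < 100")


@dataclass
class SimulationTruth:
    """Planted ground truth: the oracle for parameter-recovery tests.

    Attributes
    ----------
    cells
        One row per simulated cell: ``cell_id``, ``clone`` ("reference" for
        normal cells), ``group``, ``batch``, ``activity`` (active/inactive).
    clone_arms
        One row per (clone, arm) incl. the reference clone; diploid arms
        carry copy number 2.
    gene_sets
        Activity set name -> list of member gene ids.
    """

    cells: pd.DataFrame
    clone_arms: pd.DataFrame
    gene_sets: dict[str, list[str]]

    def copy_number(self, clone: str, arm: str) -> int:
        sub = self.clone_arms
        hit = sub[(sub["clone"] == clone) & (sub["arm"] == arm)]
        if hit.empty:
            raise KeyError(f"no copy number recorded for clone={clone!r} arm={arm!r}")
        return int(hit["copy_number"].iloc[0])


def simulate_gene_annotation(
    n_chromosomes: int,
    genes_per_arm: int,
    chrom_length: int = 100_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a gene annotation table on ``n_chromosomes`` two-arm chromosomes.

    Returns a DataFrame with columns ``gene_id, chrom, arm, start, rank``,
    sorted by (chromosome, start); starts strictly increase within each
    chromosome; each chromosome has exactly ``genes_per_arm`` genes on p
    and on q; ranks run 0..N-1 without gaps.
    """
    if n_chromosomes < 1 or genes_per_arm < 1:
        raise ValueError("n_chromosomes and genes_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    n_per_chrom = 2 * genes_per_arm
    rows = []
    for c in range(1, n_chromosomes + 1):
        # strictly increasing starts via positive jittered gaps
        jitter = rng.uniform(0.2, 1.8, size=n_per_chrom)
        starts = np.cumsum(jitter / jitter.sum() * chrom_length * 0.95).astype(np.int64)
        starts = starts + np.arange(n_per_chrom)  # guarantee strict increase
        for j in range(n_per_chrom):
            arm = "p" if j < genes_per_arm else "q"
            rows.append(
                {
                    "gene_id": f"G{c:02d}-{j:04d}",
                    "chrom": str(c),
                    "arm": f"{c}{arm}",
                    "start": int(starts[j]),
                }
            )
    ann = pd.DataFrame(rows)
    ann = ann.sort_values(["chrom", "start"], kind="stable", key=_chrom_sort_key)
    ann = ann.reset_index(drop=True)
    ann["rank"] = np.arange(len(ann))
    return ann


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "chrom":
        return col.astype(int)
    return col


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def simulate_counts(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[AnnData, SimulationTruth]:
    """Sample a count matrix with planted clones, batches and activity.

    Returns an :class:`anndata.AnnData` (raw integer counts in ``X``, cell
    metadata in ``obs``, gene annotation + symbols in ``var``) and the
    :class:`SimulationTruth` oracle.
    """
    config.validate()
    expected = 2 * config.n_chromosomes * config.genes_per_arm
    if len(annotation) != expected:
        raise ValueError(
            f"annotation has {len(annotation)} genes, config implies {expected}"
        )
    arms = list(dict.fromkeys(annotation["arm"]))
    for clone in config.clones:
        unknown = set(clone.arm_events) - set(arms)
        if unknown:
            raise ValueError(
                f"clone {clone.name!r} references unknown arm(s): {sorted(unknown)}"
            )

    rng = np.random.default_rng(config.seed)
    G = len(annotation)
    gene_ids = annotation["gene_id"].to_numpy()

    # --- per-gene baseline means, normalised so E[library] = L_i
    mu = rng.lognormal(0.0, config.baseline_logmean_sd, size=G)
    mu /= mu.sum()

    # --- mitochondrial genes (flagged by MT- symbol prefix)
    n_mito = int(round(config.mito_gene_fraction * G))
    mito_idx = rng.choice(G, size=n_mito, replace=False) if n_mito else np.array([], int)
    is_mito = np.zeros(G, bool)
    is_mito[mito_idx] = True
    symbols = np.array(
        [("MT-" + g) if m else g for g, m in zip(gene_ids, is_mito)], dtype=object
    )

    # --- activity gene sets: disjoint draws from non-mito genes
    gene_sets: dict[str, list[str]] = {}
    pool = rng.permutation(np.flatnonzero(~is_mito))
    cursor = 0
    set_member = np.zeros(G, bool)
    for set_name, size in config.activity_gene_sets.items():
        if cursor + size > len(pool):
            raise ValueError("activity gene sets exceed the non-mitochondrial gene pool")
        idx = np.sort(pool[cursor : cursor + size])
        cursor += size
        gene_sets[set_name] = [str(g) for g in gene_ids[idx]]
        set_member[idx] = True

    # --- cells: reference first, then clones in declared order
    clone_names = ["reference"] + [c.name for c in config.clones]
    n_cells_per = [config.n_reference_cells] + [c.n_cells for c in config.clones]
    n_cells = int(sum(n_cells_per))
    clone_of = np.repeat(clone_names, n_cells_per)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)

    # --- active labels: round(n_cells * active_fraction) per clone
    active = np.zeros(n_cells, bool)
    offset = config.n_reference_cells
    for clone in config.clones:
        k = int(round(clone.n_cells * clone.active_fraction))
        chosen = rng.choice(clone.n_cells, size=k, replace=False)
        active[offset + chosen] = True
        offset += clone.n_cells

    # --- batch assignment by largest-remainder allocation, then shuffled
    batch_counts = _largest_remainder_counts(
        n_cells, [b.cell_fraction for b in config.batches]
    )
    batch_of = np.repeat([b.name for b in config.batches], batch_counts)
    batch_of = batch_of[rng.permutation(n_cells)]
    batch_factors = {
        b.name: (
            rng.lognormal(0.0, b.effect_sd, size=G) if b.effect_sd > 0 else np.ones(G)
        )
        for b in config.batches
    }

    # --- copy-number profile per clone, expanded to genes
    arm_of_gene = annotation["arm"].to_numpy()
    cn_rows = []
    clone_cn_genes: dict[str, np.ndarray] = {}
    for name in clone_names:
        events = {} if name == "reference" else next(
            c for c in config.clones if c.name == name
        ).arm_events
        cn_arm = {a: int(events.get(a, 2)) for a in arms}
        clone_cn_genes[name] = np.array([cn_arm[a] for a in arm_of_gene], dtype=float)
        cn_rows.extend(
            {"clone": name, "arm": a, "copy_number": cn_arm[a]} for a in arms
        )

    # --- expected counts and Gamma–Poisson sampling, clone by clone
    L = rng.lognormal(
        math.log(config.mean_library_size) - 0.5 * config.library_size_logsd**2,
        config.library_size_logsd,
        size=n_cells,
    )
    mito_target = rng.uniform(*config.mito_pct_range, size=n_cells) / 100.0
    theta = config.nb_dispersion
    X = np.zeros((n_cells, G), dtype=np.int64)
    if config.dosage_exponent == 0:
        # alpha = 0 decouples expression from copy number entirely
        # (0**0 := 1 would otherwise still zero out a planted-zero arm)
        dosage = {name: np.ones(G) for name in clone_cn_genes}
    else:
        dosage = {
            name: (cn / 2.0) ** config.dosage_exponent
            for name, cn in clone_cn_genes.items()
        }
    mu_mito_sum = mu[is_mito].sum() if n_mito else 1.0
    for i in range(n_cells):
        lam = L[i] * mu * dosage[clone_of[i]] * batch_factors[batch_of[i]]
        if active[i] and set_member.any():
            lam = lam * np.where(set_member, config.activity_fold, 1.0)
        if n_mito:
            non_mito_total = lam[~is_mito].sum()
            f = mito_target[i]
            lam[is_mito] = (f / (1.0 - f)) * non_mito_total * mu[is_mito] / mu_mito_sum
        shape_ok = lam > 0
        lam_pos = lam[shape_ok]
        X[i, shape_ok] = rng.poisson(rng.gamma(theta, lam_pos / theta))

    obs = pd.DataFrame(
        {
            "clone": pd.Categorical(clone_of, categories=clone_names),
            "group": pd.Categorical(
                np.where(clone_of == "reference", "reference", "tumor"),
                categories=["reference", "tumor"],
            ),
            "batch": pd.Categorical(batch_of, categories=[b.name for b in config.batches]),
            "activity_true": pd.Categorical(
                np.where(active, "active", "inactive"),
                categories=["inactive", "active"],
            ),
            "mito_pct_true": mito_target * 100.0,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = annotation.set_index("gene_id").copy()
    var["symbol"] = symbols
    var["is_mito"] = is_mito
    var["in_activity_set"] = set_member

    adata = AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    adata.uns["simulation"] = {"config": asdict(config)}

    truth = SimulationTruth(
        cells=obs.reset_index()[["cell_id", "clone", "group", "batch", "activity_true"]]
        .rename(columns={"activity_true": "activity"})
        .astype({"clone": str, "group": str, "batch": str, "activity": str}),
        clone_arms=pd.DataFrame(cn_rows),
        gene_sets=gene_sets,
    )
    return adata, truth


def default_config(seed: int = 0) -> SimulationConfig:
    """The bundled study configuration: ~1,200 cells, 4 chromosomes, 3 clones.

    Clones carry 0, 1 and 3 altered arms respectively, so CNV burden is
    strictly ordered across clones; two batches with a mild multiplicative
    effect; four 40-gene activity sets (proliferation, DNA repair, DNA
    damage, cell cycle).
    """
    return SimulationConfig(
        n_chromosomes=4,
        genes_per_arm=60,
        n_reference_cells=400,
        clones=[
            CloneSpec("clone_low", 260, {}, active_fraction=0.1),
            CloneSpec("clone_mid", 260, {"1q": 4}, active_fraction=0.4),
            CloneSpec(
                "clone_high",
                280,
                {"2p": 4, "3q": 1, "4p": 3},
                active_fraction=0.7,
            ),
        ],
        batches=[BatchSpec("batchA", 0.5, 0.15), BatchSpec("batchB", 0.5, 0.15)],
        activity_gene_sets={
            "proliferation": 40,
            "dna_repair": 40,
            "dna_damage": 40,
            "cell_cycle": 40,
        },
        seed=seed,
    )
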
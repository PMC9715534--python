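"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates the shape of the study design this package
analyzes: a 20-sample atlas over seven tissues (three replicates each,
two for floral bud), a two-morph floral contrast with negative-binomially
distributed counts (variance mu + alpha * mu^2), a three-species
orthology structure with single-copy one-to-one chains to a label-bearing
outgroup species, and a PIF-style label list whose odds are inflated on
morph-responsive genes by a configurable factor theta.

All randomness flows from the single config seed; per-stage generators
are spawned deterministically from it, so every artifact is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountMatrix, write_counts_tsv, write_metadata_tsv
from .orthology import (OrthogroupTable, StratifiedDEGSets, write_ortholog_map,
                        write_orthogroups)

DEFAULT_TISSUES = (
    ("root", 3),
    ("seed", 3),
    ("seedling", 3),
    ("leaf", 3),
    ("inflorescence_stem", 3),
    ("floral_bud", 2),
    ("flower", 3),
)

SPECIES_PREFIX = {"Pveris": "pve", "Fesculentum": "fes", "Tsubulata": "tsu",
                  "Athaliana": "ath"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_genes: int = 2000
    tissues: tuple[tuple[str, int], ...] = DEFAULT_TISSUES
    morph_tissue: str = "style"
    morph_replicates: int = 3
    baseline_log_mean: float = 5.0     # ln scale; exp(5) ~ 148 counts
    baseline_log_sd: float = 1.5
    dispersion_log_mean: float = math.log(0.1)
    dispersion_log_sd: float = 0.5
    morph_responsive_frac: float = 0.05
    morph_log2fc: float = 2.0
    tissue_specific_frac: float = 0.2
    tissue_log2fc: float = 3.0
    constitutive_frac: float = 0.05
    constitutive_baseline_log_mean: float = 6.0
    constitutive_baseline_log_sd: float = 0.3
    constitutive_dispersion: float = 0.005
    library_size_range: tuple[float, float] = (0.5, 2.0)
    species: tuple[str, ...] = ("Pveris", "Fesculentum", "Tsubulata")
    outgroup: str = "Athaliana"
    n_orthogroups: int = 600
    single_copy_frac: float = 0.7
    og_extra_gene_rate: float = 1.0
    n_planted_shared: int = 2
    planted_log2fc: float = 3.0
    n_extra_degs: int = 30
    set_base_rate: float = 0.05
    set_enrichment_odds: float = 1.0

    def validate(self) -> None:
        fractions = {
            "morph_responsive_frac": self.morph_responsive_frac,
            "tissue_specific_frac": self.tissue_specific_frac,
            "constitutive_frac": self.constitutive_frac,
            "single_copy_frac": self.single_copy_frac,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.set_base_rate < 1.0:
            raise ValueError(f"set_base_rate must be in (0, 1), got {self.set_base_rate}")
        positives = {
            "n_genes": self.n_genes,
            "morph_replicates": self.morph_replicates,
            "baseline_log_sd": self.baseline_log_sd,
            "constitutive_dispersion": self.constitutive_dispersion,
            "n_orthogroups": self.n_orthogroups,
            "set_enrichment_odds": self.set_enrichment_odds,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"library_size_range must be 0 < lo <= hi, got {self.library_size_range}")
        if len(self.species) < 2:
            raise ValueError("species roster needs at least 2 species")
        if not self.tissues or any(n < 1 for _, n in self.tissues):
            raise ValueError("tissues need at least one replicate each")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def _gene_ids(species: str, n: int) -> list[str]:
    prefix = SPECIES_PREFIX.get(species, species.lower()[:3])
    return [f"{prefix}_g{i:05d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2) draws; Poisson when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        n = 1.0 / alpha[~tiny]
        p = n / (n + mean[~tiny])
        out[~tiny] = rng.negative_binomial(n, p)
    return out


def simulate_counts(cfg: SimulationConfig, gene_ids: list[str] | None = None,
                    forced_up_genes: set[str] | None = None,
                    ) -> tuple[CountMatrix, pd.DataFrame, pd.Series]:
    """Atlas + morph-contrast count matrix with per-gene ground truth.

    Returns (CountMatrix, gene truth table, library multipliers). The
    truth table records baseline mean, dispersion, the tissue a specific
    gene is boosted in, the true morph log2 fold change (S over L), and
    the constitutive flag. Atlas samples carry morph "pooled" and group
    "atlas"; the extra morph-contrast samples carry morph L/S and group
    "morph_contrast".
    """
    cfg.validate()
    rng = cfg.rng(1)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(1, cfg.n_genes + 1)]
    n = len(gene_ids)

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n))
    alpha = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, n))

    roles = rng.permutation(n)
    n_const = int(round(cfg.constitutive_frac * n))
    n_resp = int(round(cfg.morph_responsive_frac * n))
    n_spec = int(round(cfg.tissue_specific_frac * n))
    const_idx = roles[:n_const]
    resp_idx = roles[n_const:n_const + n_resp]
    spec_idx = roles[n_const + n_resp:n_const + n_resp + n_spec]

    baseline[const_idx] = np.exp(rng.normal(
        cfg.constitutive_baseline_log_mean, cfg.constitutive_baseline_log_sd,
        len(const_idx)))
    alpha[const_idx] = cfg.constitutive_dispersion

    tissue_names = [t for t, _ in cfg.tissues]
    spec_tissue = np.full(n, "", dtype=object)
    spec_tissue[spec_idx] = rng.choice(tissue_names, size=len(spec_idx))

    morph_lfc = np.zeros(n)
    signs = np.where(np.arange(len(resp_idx)) % 2 == 0, 1.0, -1.0)
    morph_lfc[resp_idx] = signs * cfg.morph_log2fc
    if forced_up_genes:
        forced = np.isin(np.array(gene_ids, dtype=object), sorted(forced_up_genes))
        # planted genes are strong, expressed responders, or the planted
        # signal is ill-posed under the small per-morph replicate numbers
        morph_lfc[forced] = abs(cfg.planted_log2fc)
        baseline[forced] = np.maximum(baseline[forced],
                                      math.exp(cfg.baseline_log_mean))

    samples, tissue_of, morph_of, group_of = [], [], [], []
    for tissue, reps in cfg.tissues:
        for r in range(1, reps + 1):
            samples.append(f"{tissue}_rep{r}")
            tissue_of.append(tissue)
            morph_of.append("pooled")
            group_of.append("atlas")
    for morph in ("L", "S"):
        for r in range(1, cfg.morph_replicates + 1):
            samples.append(f"{cfg.morph_tissue}_{morph}_rep{r}")
            tissue_of.append(cfg.morph_tissue)
            morph_of.append(morph)
            group_of.append("morph_contrast")

    lo, hi = cfg.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))

    mu = np.tile(baseline[:, None], (1, len(samples)))
    for j, (tissue, morph) in enumerate(zip(tissue_of, morph_of)):
        boost = np.ones(n)
        boost[spec_tissue == tissue] = 2.0 ** cfg.tissue_log2fc
        if morph == "S":
            boost = boost * 2.0 ** morph_lfc
        mu[:, j] = mu[:, j] * boost * lib[j]
    counts = _nb_draw(rng, mu, alpha[:, None])

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples)
    metadata = pd.DataFrame({
        "tissue": tissue_of,
        "morph": morph_of,
        "species": cfg.species[0],
        "group": group_of,
    }, index=pd.Index(samples, name="sample_id"))
    truth = pd.DataFrame({
        "baseline": baseline,
        "dispersion": alpha,
        "specific_tissue": spec_tissue,
        "morph_log2fc": morph_lfc,
        "constitutive": np.isin(np.arange(n), const_idx),
        "seed": cfg.seed,
    }, index=pd.Index(gene_ids, name="gene_id"))
    lib_s = pd.Series(lib, index=samples, name="library_multiplier")
    return CountMatrix(counts_df, metadata), truth, lib_s


@dataclass
class OrthologyTruth:
    gene_to_og: dict[str, dict[str, str]]          # species -> gene -> og
    true_pairs: dict[str, dict[str, str]]          # species -> gene -> outgroup gene
    single_copy_ogs: tuple[str, ...]
    seed: int


def simulate_orthology(cfg: SimulationConfig,
                       ) -> tuple[OrthogroupTable, dict[str, dict[str, str]], OrthologyTruth]:
    """Orthogroups over the roster + outgroup, with true one-to-one chains.

    A ``single_copy_frac`` share of orthogroups holds exactly one gene per
    species (including the outgroup): these define the true one-to-one
    ortholog chains and the per-species maps to the outgroup. Remaining
    orthogroups get per-species gene numbers drawn from a shifted-Poisson
    law and contribute no one-to-one pairs.
    """
    cfg.validate()
    rng = cfg.rng(2)
    roster = (*cfg.species, cfg.outgroup)
    n_single = int(round(cfg.single_copy_frac * cfg.n_orthogroups))
    counters = {sp: 0 for sp in roster}

    def next_gene(sp: str) -> str:
        counters[sp] += 1
        prefix = SPECIES_PREFIX.get(sp, sp.lower()[:3])
        return f"{prefix}_g{counters[sp]:05d}"

    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    gene_to_og: dict[str, dict[str, str]] = {sp: {} for sp in roster}
    true_pairs: dict[str, dict[str, str]] = {sp: {} for sp in cfg.species}
    single_ids = []
    for k in range(1, cfg.n_orthogroups + 1):
        og_id = f"OG{k:07d}"
        members: dict[str, tuple[str, ...]] = {}
        if k <= n_single:
            outgroup_gene = None
            for sp in roster:
                g = next_gene(sp)
                members[sp] = (g,)
                gene_to_og[sp][g] = og_id
                if sp == cfg.outgroup:
                    outgroup_gene = g
            for sp in cfg.species:
                true_pairs[sp][members[sp][0]] = outgroup_gene
            single_ids.append(og_id)
        else:
            sizes = rng.poisson(cfg.og_extra_gene_rate, len(roster))
            while sizes.sum() < 2:
                sizes = rng.poisson(cfg.og_extra_gene_rate, len(roster))
            for sp, size in zip(roster, sizes):
                if size == 0:
                    continue
                genes = tuple(next_gene(sp) for _ in range(size))
                members[sp] = genes
                for g in genes:
                    gene_to_og[sp][g] = og_id
        groups[og_id] = members
    table = OrthogroupTable(groups, roster)
    truth = OrthologyTruth(gene_to_og, true_pairs, tuple(single_ids), cfg.seed)
    return table, dict(true_pairs), truth


def simulate_rbh_scores(true_pairs: dict[str, str], cfg: SimulationConfig,
                        n_decoys: int = 2) -> pd.DataFrame:
    """Bitscore-like (query, target, score) table around known true pairs.

    True pairs score high; each query also hits ``n_decoys`` random wrong
    targets with lower but overlapping scores, so reciprocal-best-hit
    reduction recovers most but not necessarily all true pairs.
    """
    cfg.validate()
    rng = cfg.rng(3)
    queries = sorted(true_pairs)
    targets = sorted(set(true_pairs.values()))
    rows = []
    for q in queries:
        t_true = true_pairs[q]
        rows.append((q, t_true, rng.uniform(200.0, 400.0)))
        decoys = rng.choice(targets, size=min(n_decoys, len(targets)), replace=False)
        for t in decoys:
            if t == t_true:
                continue
            rows.append((q, t, rng.uniform(50.0, 210.0)))
    return pd.DataFrame(rows, columns=["query", "target", "score"])


def simulate_set_labels(cfg: SimulationConfig, ortholog_map: dict[str, str],
                        responsive_genes: set[str]) -> tuple[set[str], dict]:
    """Label outgroup genes; responsive genes' orthologs get theta-fold odds.

    Base labelling rate r = ``set_base_rate``; an outgroup gene whose
    species ortholog is morph-responsive is labelled with probability
    theta*r / (1 - r + theta*r), i.e. odds multiplied by theta =
    ``set_enrichment_odds``.
    """
    cfg.validate()
    rng = cfg.rng(4)
    r = cfg.set_base_rate
    theta = cfg.set_enrichment_odds
    p_resp = theta * r / (1.0 - r + theta * r)
    labels: set[str] = set()
    for gene in sorted(ortholog_map):
        outgroup_gene = ortholog_map[gene]
        p = p_resp if gene in responsive_genes else r
        if rng.random() < p:
            labels.add(outgroup_gene)
    truth = {"base_rate": r, "theta": theta, "p_responsive": p_resp,
             "seed": cfg.seed}
    return labels, truth


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, with the truth to check it against."""

    config: SimulationConfig
    count_matrix: CountMatrix
    gene_truth: pd.DataFrame
    library_multipliers: pd.Series
    orthogroups: OrthogroupTable
    ortholog_maps: dict[str, dict[str, str]]
    orthology_truth: OrthologyTruth
    deg_truth: StratifiedDEGSets
    planted_shared_ogs: tuple[str, ...]
    labels: set[str]
    label_truth: dict


def simulate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """One coherent synthetic study: orthology, counts, DEG strata, labels.

    The focal species (first of the roster) gets the simulated count
    matrix over its own orthology-derived gene ids. ``n_planted_shared``
    single-copy orthogroups are made morph-responsive (up, female organs)
    in all species, so the triple-intersection Venn cell has a known
    answer; the remaining morph-responsive focal genes and
    ``n_extra_degs`` random genes per non-focal species fill the other
    cells. Labels are drawn on the outgroup via the focal one-to-one map.
    """
    cfg.validate()
    table, maps, otruth = simulate_orthology(cfg)
    focal = cfg.species[0]
    focal_genes = sorted(otruth.gene_to_og[focal])

    rng = cfg.rng(5)
    planted = tuple(sorted(
        rng.choice(otruth.single_copy_ogs,
                   size=min(cfg.n_planted_shared, len(otruth.single_copy_ogs)),
                   replace=False)
    ))
    planted_focal = {table.genes(og, focal)[0] for og in planted}
    cm, gene_truth, lib = simulate_counts(cfg, gene_ids=focal_genes,
                                          forced_up_genes=planted_focal)

    degs = StratifiedDEGSets({sp: {"female": {"up": set(), "down": set()}}
                              for sp in cfg.species})
    up = set(gene_truth.index[gene_truth["morph_log2fc"] > 0])
    down = set(gene_truth.index[gene_truth["morph_log2fc"] < 0])
    degs.add(focal, "female", "up", up)
    degs.add(focal, "female", "down", down)
    for sp in cfg.species[1:]:
        sp_genes = sorted(otruth.gene_to_og[sp])
        sp_up = {table.genes(og, sp)[0] for og in planted}
        extra = rng.choice(sp_genes, size=min(cfg.n_extra_degs, len(sp_genes)),
                           replace=False)
        degs.add(sp, "female", "up", sp_up | set(extra))

    responsive = up | down
    labels, ltruth = simulate_set_labels(cfg, maps[focal], responsive)
    return SyntheticBundle(
        config=cfg, count_matrix=cm, gene_truth=gene_truth,
        library_multipliers=lib, orthogroups=table, ortholog_maps=maps,
        orthology_truth=otruth, deg_truth=degs, planted_shared_ogs=planted,
        labels=labels, label_truth=ltruth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write the bundle as plain-text files; returns {artifact: path}.

    Emits counts.tsv, metadata.tsv, orthogroups.tsv, one ortholog-map TSV
    per species, the label gene list, per-stratum DEG lists for the
    non-focal species, and gene-level truth TSVs.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    write_counts_tsv(bundle.count_matrix.counts, _p("counts.tsv"))
    write_metadata_tsv(bundle.count_matrix.metadata, _p("metadata.tsv"))
    write_orthogroups(bundle.orthogroups, _p("orthogroups.tsv"))
    for sp, mapping in bundle.ortholog_maps.items():
        write_ortholog_map(mapping, _p(f"orthologs_{sp}.tsv"))
    with open(_p("label_genes.txt"), "w") as fh:
        fh.write("# synthetic label gene list (outgroup ids)\n")
        for g in sorted(bundle.labels):
            fh.write(f"{g}\n")
    for sp in bundle.config.species:
        for direction in ("up", "down"):
            genes = sorted(bundle.deg_truth.get(sp, "female", direction))
            if not genes and sp != bundle.config.species[0]:
                continue
            with open(_p(f"degs_{sp}_female_{direction}.txt"), "w") as fh:
                for g in genes:
                    fh.write(f"{g}\n")
    bundle.gene_truth.to_csv(_p("truth_genes.tsv"), sep="\t")
    bundle.library_multipliers.rename_axis("sample_id").to_csv(
        _p("truth_library.tsv"), sep="\t")
    with open(_p("truth_planted.txt"), "w") as fh:
        for og in bundle.planted_shared_ogs:
            fh.write(f"{og}\n")
    return paths
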
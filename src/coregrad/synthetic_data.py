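"""Synthetic fruit-fly gut/pulp community generator with known ground truth.

Emulates a two-transect field design: 6 latitudinal sites (17.5-22.5 °N at
low altitude) and 10 altitudinal sites (100-1,900 masl at fixed latitude),
each sampled for larvae, newly emerged females and males, and host-fruit
pulp, 5 replicates per stage per site.  Counts follow a
Dirichlet-multinomial around an expected composition built from a log-normal
base composition plus planted structure —

* genus-latitude log-linear slopes (log2 relative abundance per °N; by
  default Acetobacter, Gluconobacter and Lactobacillus increase and
  Phyllobacterium decreases with latitude, applied to fly stages); effects
  are planted share-wise, the unplanted features absorbing the complement,
  so a planted genus's log2 relative abundance is exactly linear in latitude
  and a log-TSS linear model is correctly specified,
* a stage-composition shift separating larval, adult and pulp communities,
* planted core features whose occupancy (presence) is drawn Bernoulli per
  sample independently of abundance, so core membership ground truth is
  controlled separately from sequencing depth.

Sequencing depth is Poisson around 20,000 reads for fly samples and 2,000
for pulp (pre-normalization).  A few chloroplast/mitochondria features are
included to exercise contaminant filtering.  Everything is reproducible from
the config seed, and a GroundTruth object records every planted quantity for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

from coregrad._utils import as_rng, derive_seed
from coregrad.data_model import RANKS, FeatureTable

FLY_STAGES = ("larva", "female", "male")

#: (phylum, class, order, family, genus) for the synthetic genus pool.
GENUS_POOL: tuple[tuple[str, str, str, str, str], ...] = (
    ("Proteobacteria", "Alphaproteobacteria", "Acetobacterales", "Acetobacteraceae", "Acetobacter"),
    ("Proteobacteria", "Alphaproteobacteria", "Acetobacterales", "Acetobacteraceae", "Gluconobacter"),
    ("Proteobacteria", "Alphaproteobacteria", "Acetobacterales", "Acetobacteraceae", "Komagataeibacter"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae", "Phyllobacterium"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Brucellaceae", "Brucella"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Enterobacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Erwiniaceae", "Pantoea"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Erwiniaceae", "Tatumella"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Kosakonia"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Alcaligenaceae", "Achromobacter"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Leuconostoc"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Lactococcus"),
    ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
)

DEFAULT_SLOPES: dict[str, float] = {
    "Acetobacter": 0.3,
    "Gluconobacter": 0.2,
    "Lactobacillus": 0.15,
    "Phyllobacterium": -0.3,
}

#: preferred host genera for planted core features, mirroring the taxa a
#: tephritid gut survey reports as core members.
CORE_GENERA = {
    "larva_only": ("Gluconobacter", "Acetobacter", "Phyllobacterium"),
    "adult_only": ("Enterobacter", "Brucella"),
    "shared": ("Phyllobacterium", "Achromobacter"),
}


@dataclass(frozen=True)
class CoreFeatureSpec:
    """Planted core membership: per stage-group occupancy and a target mean share."""

    occupancy: Mapping[str, float]  # stage-group ("larva"/"adult"/"pulp") -> prob
    mean_abundance: float


@dataclass(frozen=True)
class SimulationConfig:
    n_sites_lat: int = 6
    n_sites_alt: int = 10
    replicates_per_stage_site: int = 5
    stages: tuple[str, ...] = ("larva", "female", "male", "pulp")
    n_features: int = 300
    n_contaminants: int = 5
    depth_fly: int = 20_000
    depth_pulp: int = 2_000
    dirichlet_concentration: float = 200.0
    core_occupancy: float = 0.95
    other_occupancy: float = 0.5
    pulp_core_occupancy: float = 0.70
    core_mean_abundance: float = 0.02
    n_core_larva_only: int = 7
    n_core_adult_only: int = 3
    n_core_shared: int = 2
    planted_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES)
    )
    #: minimum community share of each planted-gradient genus in the base
    #: composition; gradient-responsive genera in tephritid gut surveys are
    #: among the abundant community members (>1% mean relative abundance)
    slope_genus_min_share: float = 0.02
    planted_stage_shift: float = 1.5
    planted_core: Mapping[str, CoreFeatureSpec] | None = None
    latitude_range: tuple[float, float] = (17.5, 22.5)
    altitude_range: tuple[float, float] = (100.0, 1900.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_occupancy", "other_occupancy", "pulp_core_occupancy"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_fly <= 0 or self.depth_pulp <= 0:
            raise ValueError("depths must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not (0 < self.core_mean_abundance < 1):
            raise ValueError("core_mean_abundance must be in (0, 1)")
        if not (0 <= self.slope_genus_min_share < 0.5):
            raise ValueError("slope_genus_min_share must be in [0, 0.5)")
        n_core = self.n_core_larva_only + self.n_core_adult_only + self.n_core_shared
        if self.planted_core is None and n_core > self.n_features - self.n_contaminants:
            raise ValueError("more planted core features than available features")
        if self.n_contaminants >= self.n_features:
            raise ValueError("n_contaminants must leave room for bacterial features")

    @property
    def feature_ids(self) -> list[str]:
        width = max(4, len(str(self.n_features)))
        return [f"ASV{i + 1:0{width}d}" for i in range(self.n_features)]


@dataclass(frozen=True)
class GroundTruth:
    """Every planted quantity, for recovery tests against the pipeline."""

    core_features: dict[str, set[str]]  # stage-group -> planted core set
    slopes: dict[str, float]  # genus -> log2 slope per degree latitude
    cluster_labels: pd.Series  # sample -> stage-group
    expected_composition: pd.DataFrame  # features × samples, pre-occupancy softmax
    occupancy: pd.DataFrame  # features × stage-groups
    latitude_reference: float


def stage_group(stage: str) -> str:
    """Collapse stages to the composition groups larva / adult / pulp."""
    if stage == "larva":
        return "larva"
    if stage in ("female", "male"):
        return "adult"
    if stage == "pulp":
        return "pulp"
    raise ValueError(f"unknown stage '{stage}'")


def simulate_tree(
    n_features: int,
    seed: int | None = None,
    feature_ids: Sequence[str] | None = None,
) -> skbio.TreeNode:
    """Random rooted bifurcating tree by sequential random joins.

    Branch lengths are exponential with mean 0.1; deterministic given seed.
    """
    if n_features < 2:
        raise ValueError("need n_features >= 2 to build a tree")
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(n_features)]
    if len(feature_ids) != n_features:
        raise ValueError("feature_ids length must equal n_features")
    rng = as_rng(seed)
    nodes = [
        skbio.TreeNode(name=str(fid), length=float(rng.exponential(0.1)))
        for fid in feature_ids
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _assign_taxonomy(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = config.feature_ids
    n_bact = config.n_features - config.n_contaminants
    rows = {}
    weights = rng.dirichlet(np.full(len(GENUS_POOL), 1.5))
    genus_idx = np.concatenate(
        [
            np.arange(len(GENUS_POOL)),  # every genus gets at least one ASV
            rng.choice(len(GENUS_POOL), size=max(n_bact - len(GENUS_POOL), 0), p=weights),
        ]
    )[:n_bact]
    species_counter: dict[str, int] = {}
    for fid, gi in zip(ids[:n_bact], genus_idx):
        phylum, cls, order, fam, genus = GENUS_POOL[gi]
        k = species_counter.get(genus, 0) + 1
        species_counter[genus] = k
        rows[fid] = ["Bacteria", phylum, cls, order, fam, genus, f"{genus} sp{k}"]
    for j, fid in enumerate(ids[n_bact:]):
        if j % 2 == 0:
            rows[fid] = ["Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast", "", "", ""]
        else:
            rows[fid] = ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales", "Mitochondria", "", ""]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "feature_id"
    return df


def _default_core(
    config: SimulationConfig, taxonomy: pd.DataFrame
) -> dict[str, CoreFeatureSpec]:
    """Pick planted core features from the preferred genera:

    a larva-exclusive core, an adult-exclusive core, a small shared set, and
    a pulp core equal to part of the larval one at lower occupancy.
    """
    used: set[str] = set()

    def pick(genera: Sequence[str], n: int) -> list[str]:
        chosen: list[str] = []
        by_genus = {g: [f for f in taxonomy.index[taxonomy["genus"] == g] if f not in used] for g in genera}
        gi = 0
        while len(chosen) < n:
            pool = by_genus[genera[gi % len(genera)]]
            if pool:
                f = pool.pop(0)
                chosen.append(f)
                used.add(f)
            elif all(not p for p in by_genus.values()):
                spare = [f for f in taxonomy.index if taxonomy.at[f, "genus"] and f not in used]
                f = spare[0]
                chosen.append(f)
                used.add(f)
            gi += 1
        return chosen

    larva_only = pick(CORE_GENERA["larva_only"], config.n_core_larva_only)
    adult_only = pick(CORE_GENERA["adult_only"], config.n_core_adult_only)
    shared = pick(CORE_GENERA["shared"], config.n_core_shared)
    pulp_members = set(larva_only[: min(5, len(larva_only))])

    core: dict[str, CoreFeatureSpec] = {}
    for f in larva_only:
        occ = {"larva": config.core_occupancy, "adult": config.other_occupancy}
        occ["pulp"] = config.pulp_core_occupancy if f in pulp_members else config.other_occupancy
        core[f] = CoreFeatureSpec(occupancy=occ, mean_abundance=config.core_mean_abundance)
    for f in adult_only:
        core[f] = CoreFeatureSpec(
            occupancy={"larva": config.other_occupancy, "adult": config.core_occupancy, "pulp": config.other_occupancy},
            mean_abundance=config.core_mean_abundance,
        )
    for f in shared:
        core[f] = CoreFeatureSpec(
            occupancy={"larva": config.core_occupancy, "adult": config.core_occupancy, "pulp": config.other_occupancy},
            mean_abundance=config.core_mean_abundance,
        )
    return core


def _site_table(config: SimulationConfig) -> list[tuple[str, float, float, str]]:
    """(site, latitude, altitude, transect) for the two transects."""
    sites = []
    lats = np.linspace(*config.latitude_range, config.n_sites_lat)
    for i, lat in enumerate(lats, start=1):
        sites.append((f"latS{i}", float(lat), 50.0, "latitudinal"))
    alts = np.linspace(*config.altitude_range, config.n_sites_alt)
    mid_lat = float(np.mean(config.latitude_range))
    for i, alt in enumerate(alts, start=1):
        sites.append((f"altS{i}", mid_lat, float(alt), "altitudinal"))
    return sites


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[FeatureTable, pd.DataFrame, skbio.TreeNode, pd.DataFrame, GroundTruth]:
    """Generate (feature table, taxonomy, tree, metadata, ground truth)."""
    rng = as_rng(derive_seed(config.seed, "composition"))
    taxonomy = _assign_taxonomy(config, as_rng(derive_seed(config.seed, "taxonomy")))
    tree = simulate_tree(
        config.n_features,
        seed=derive_seed(config.seed, "tree"),
        feature_ids=config.feature_ids,
    )
    ids = config.feature_ids
    n = config.n_features
    genus = taxonomy["genus"]
    contaminant = (taxonomy["order"] == "Chloroplast") | (
        taxonomy["family"] == "Mitochondria"
    )

    core = dict(config.planted_core) if config.planted_core is not None else _default_core(config, taxonomy)
    unknown = sorted(set(core) - set(ids))
    if unknown:
        raise ValueError(f"planted core features not among the features: {unknown}")
    for f, spec in core.items():
        if not all(0 <= p <= 1 for p in spec.occupancy.values()):
            raise ValueError(f"occupancy probabilities for '{f}' must be in [0, 1]")

    groups = ("larva", "adult", "pulp")
    # shared log base composition + per-group shift
    z = rng.normal(0.0, 1.5, size=n)
    delta = {g: rng.normal(0.0, config.planted_stage_shift, size=n) for g in groups}

    # per-feature log2 latitude slope (fly stages only)
    slope = np.array([config.planted_slopes.get(genus[f], 0.0) for f in ids])
    lat_ref = float(np.mean(config.latitude_range))

    # occupancy per feature per group
    occupancy = pd.DataFrame(config.other_occupancy, index=ids, columns=list(groups))
    occupancy.loc[contaminant, ["larva", "adult"]] = 0.3
    occupancy.loc[contaminant, "pulp"] = 0.9
    for f, spec in core.items():
        for g, p in spec.occupancy.items():
            occupancy.at[f, g] = p

    # group base weights with core shares pinned at the reference latitude
    core_mask = np.array([f in core for f in ids])
    base_weight: dict[str, np.ndarray] = {}
    for g in groups:
        w = np.exp(z + delta[g])
        targets = np.array([core[f].mean_abundance if f in core else 0.0 for f in ids])
        total_target = targets[core_mask].sum()
        if total_target >= 1:
            raise ValueError("planted core mean abundances sum to >= 1")
        w_noncore = w[~core_mask].sum()
        w = w.copy()
        w[core_mask] = targets[core_mask] / (1 - total_target) * w_noncore
        # floor the base share of every planted-gradient genus
        for genus_name, beta in config.planted_slopes.items():
            if beta == 0.0 or config.slope_genus_min_share == 0.0:
                continue
            members = (genus == genus_name).to_numpy()
            if not members.any():
                continue
            share = w[members].sum() / w.sum()
            if share < config.slope_genus_min_share:
                target = config.slope_genus_min_share
                w[members] *= (target / (1 - target)) * (
                    w[~members].sum() / w[members].sum()
                )
        base_weight[g] = w

    # a feature is planted-core for a group when its occupancy there is
    # elevated above the background occupancy of ordinary features
    core_truth: dict[str, set[str]] = {g: set() for g in groups}
    for f, spec in core.items():
        for g, p in spec.occupancy.items():
            if p > config.other_occupancy:
                core_truth[g].add(f)

    sites = _site_table(config)
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    expected_cols: dict[str, np.ndarray] = {}
    count_cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for site, lat, alt, transect in sites:
        for stage in config.stages:
            g = stage_group(stage)
            is_fly = stage in FLY_STAGES
            w = base_weight[g]
            p0 = w / w.sum()
            if is_fly and np.any(slope != 0.0):
                # gradient effects enter share-wise: planted features' shares
                # scale by 2^(slope * delta_lat) and the null features absorb
                # the complement, so log2 relative abundance of a planted
                # genus is exactly linear in latitude (the association
                # estimator is correctly specified, with no closure term)
                planted = slope != 0.0
                s = p0 * np.exp2(slope * (lat - lat_ref))
                total_planted = s[planted].sum()
                if total_planted >= 0.95:
                    raise ValueError(
                        "planted gradient effects push the planted genera to "
                        f">=95% of the community at latitude {lat}; reduce the "
                        "slopes or the planted genera's base abundance"
                    )
                s[~planted] = p0[~planted] * (1 - total_planted) / (
                    1 - p0[planted].sum()
                )
                p_expected = s / s.sum()
            else:
                p_expected = p0
            occ = occupancy[g].to_numpy()
            depth_mean = config.depth_fly if is_fly else config.depth_pulp
            for rep in range(1, config.replicates_per_stage_site + 1):
                sid = f"{site}_{stage}_r{rep}"
                mask = rng.random(n) < occ
                if not mask.any():  # vanishing-probability guard
                    mask[int(np.argmax(p_expected))] = True
                p = np.where(mask, p_expected, 0.0)
                p = p / p.sum()
                support = p > 0
                if np.isinf(config.dirichlet_concentration):
                    realized = p
                else:
                    realized = np.zeros(n)
                    realized[support] = rng.dirichlet(
                        config.dirichlet_concentration * p[support]
                    )
                depth = max(int(rng.poisson(depth_mean)), 1)
                counts = np.zeros(n, dtype=np.int64)
                counts[support] = rng.multinomial(
                    depth, realized[support] / realized[support].sum()
                )
                sample_ids.append(sid)
                count_cols[sid] = counts
                expected_cols[sid] = p_expected
                labels[sid] = g
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "stage": stage,
                        "site": site,
                        "latitude_deg_n": lat,
                        "altitude_masl": alt,
                        "transect": transect,
                    }
                )

    table = FeatureTable(
        pd.DataFrame(count_cols, index=pd.Index(ids, name="feature_id"), dtype=np.int64)
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        core_features=core_truth,
        slopes={g_: s for g_, s in config.planted_slopes.items()},
        cluster_labels=pd.Series(labels, name="stage_group"),
        expected_composition=pd.DataFrame(
            expected_cols, index=pd.Index(ids, name="feature_id")
        ),
        occupancy=occupancy,
        latitude_reference=lat_ref,
    )
    return table, taxonomy, tree, metadata, truth
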
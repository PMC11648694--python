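"""End-to-end pipeline: simulate/load → filter → normalize → UniFrac →
ordination/clusters → PERMANOVA → composition → associations → LEfSe → core.

Driven by a PipelineConfig (YAML-loadable); every intermediate is written as
TSV into the output directory together with a manifest of artifact checksums
and a plain-text run log (parameters, stage seeds, versions — no timestamps,
so re-running an identical config is byte-identical).  Each analysis stage
gets a seed derived by hashing the master seed with the stage name: adding a
stage never perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from coregrad._utils import derive_seed
from coregrad.beta_diversity import pcoa, unifrac_matrix
from coregrad.core_microbiota import CoreParams, core_intersections, group_cores
from coregrad.data_model import (
    DEFAULT_EXCLUDE_TERMS,
    FeatureTable,
    collapse_taxonomy,
    family_composition,
    filter_taxa,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_distance_matrix,
    write_feature_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from coregrad.differential_abundance import fit_gradient_models, lefse_scores
from coregrad.group_inference import gap_statistic, kmeans_cluster, permanova
from coregrad.normalization import SrsParams, srs_normalize_table
from coregrad.synthetic_data import (
    FLY_STAGES,
    SimulationConfig,
    simulate_dataset,
    stage_group,
)

TRANSECT_COVARIATE = {"altitudinal": "altitude_masl", "latitudinal": "latitude_deg_n"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full analysis run.

    Input paths may be omitted, in which case a synthetic dataset is
    generated from `simulation` overrides (and its ground truth written
    alongside the inputs).
    """

    feature_table: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    metadata: str | None = None
    simulation: Mapping[str, Any] = field(default_factory=dict)
    exclude_terms: tuple[str, ...] = DEFAULT_EXCLUDE_TERMS
    srs_depth_fly: int = 5000
    srs_depth_pulp: int = 500
    permanova_covariates: tuple[str, ...] = ("latitude_deg_n", "altitude_masl")
    n_permutations: int = 999
    gap_k_max: int = 8
    gap_b: int = 100
    gap_embed: str = "distance"  # "distance" rows (literal) or "pcoa" coordinates
    association_min_prevalence: float = 0.10
    lefse_alpha: float = 0.05
    lefse_lda_threshold: float = 2.0
    core_n_boot: int = 1000
    core_support: float = 0.95
    core_prevalence: float = 0.75
    core_prevalence_pulp: float = 0.65
    family_min_mean_abundance: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise PipelineError(f"unknown config keys: {unknown}")
        for key in ("exclude_terms", "permanova_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["exclude_terms"] = list(self.exclude_terms)
        d["permanova_covariates"] = list(self.permanova_covariates)
        d["simulation"] = dict(self.simulation)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, str]:
    """Execute the full analysis; returns {artifact name: sha256}.

    Any stage error aborts with a PipelineError naming the stage; artifacts
    written so far are retained and a FAILED marker file records the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    log_lines: list[str] = [
        f"coregrad {__import__('importlib.metadata', fromlist=['version']).version('coregrad')}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        "config:",
        yaml.safe_dump(config.to_dict(), sort_keys=True).rstrip(),
        "",
    ]
    current_stage = "setup"

    def record(path: Path) -> None:
        artifacts.append(path)

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        # ------------------------------------------------------------ inputs
        current_stage = "inputs"
        paths = (config.feature_table, config.taxonomy, config.tree, config.metadata)
        if any(p is not None for p in paths):
            if not all(p is not None for p in paths):
                raise ValueError(
                    "provide all four input paths (feature_table, taxonomy, tree, "
                    "metadata) or none (to simulate)"
                )
            table = read_feature_table(paths[0])
            taxonomy = read_taxonomy(paths[1])
            tree = read_tree(paths[2])
            metadata = read_metadata(paths[3])
            truth = None
            log("inputs: loaded from files")
        else:
            sim_conf = SimulationConfig(
                **{"seed": derive_seed(config.seed, "simulate"), **dict(config.simulation)}
            )
            table, taxonomy, tree, metadata, truth = simulate_dataset(sim_conf)
            log(f"inputs: simulated (seed {sim_conf.seed})")
            write_feature_table(table, out / "input_feature_table.tsv")
            write_taxonomy(taxonomy, out / "input_taxonomy.tsv")
            write_tree(tree, out / "input_tree.nwk")
            write_metadata(metadata, out / "input_metadata.tsv")
            for p in ("input_feature_table.tsv", "input_taxonomy.tsv", "input_tree.nwk", "input_metadata.tsv"):
                record(out / p)
            truth_core = pd.DataFrame(
                [
                    {"group": g, "feature_id": f}
                    for g, fs in truth.core_features.items()
                    for f in sorted(fs)
                ]
            )
            _write_tsv(truth_core, out / "ground_truth_core.tsv", index=False)
            record(out / "ground_truth_core.tsv")
            truth_slopes = pd.DataFrame(
                sorted(truth.slopes.items()), columns=["genus", "log2_slope_per_degree"]
            )
            _write_tsv(truth_slopes, out / "ground_truth_slopes.tsv", index=False)
            record(out / "ground_truth_slopes.tsv")

        missing_cols = [
            c for c in config.permanova_covariates if c not in metadata.columns
        ]
        if missing_cols:
            raise ValueError(f"metadata lacks configured columns: {missing_cols}")
        extra = [s for s in table.sample_ids if s not in metadata.index]
        if extra:
            raise ValueError(f"samples missing from metadata: {extra}")

        # ------------------------------------------------------------ filter
        current_stage = "filter_taxa"
        filtered = filter_taxa(table, taxonomy, config.exclude_terms)
        write_feature_table(filtered, out / "filtered_table.tsv")
        record(out / "filtered_table.tsv")
        log(
            f"filter_taxa: {table.shape[0]} -> {filtered.shape[0]} features "
            f"(excluded terms: {list(config.exclude_terms)})"
        )

        # --------------------------------------------------------- normalize
        current_stage = "normalize"
        meta = metadata.loc[filtered.sample_ids]
        fly_samples = [s for s in filtered.sample_ids if meta.at[s, "stage"] in FLY_STAGES]
        pulp_samples = [s for s in filtered.sample_ids if meta.at[s, "stage"] == "pulp"]
        norm: dict[str, FeatureTable] = {}
        exclusions: list[dict] = []
        for name, samples, depth in (
            ("fly", fly_samples, config.srs_depth_fly),
            ("pulp", pulp_samples, config.srs_depth_pulp),
        ):
            if not samples:
                continue
            sub = filtered.select_samples(samples)
            normalized, excluded = srs_normalize_table(sub, SrsParams(c_min=depth))
            norm[name] = normalized
            exclusions.extend(
                {"sample_id": s, "class": name, "reason": f"total below {depth}"}
                for s in excluded
            )
            write_feature_table(normalized, out / f"normalized_{name}.tsv")
            record(out / f"normalized_{name}.tsv")
            log(f"normalize ({name}): SRS to {depth}; excluded {len(excluded)} sample(s)")
        _write_tsv(
            pd.DataFrame(exclusions, columns=["sample_id", "class", "reason"]),
            out / "normalization_exclusions.tsv",
            index=False,
        )
        record(out / "normalization_exclusions.tsv")

        # ----------------------------------------------------- beta diversity
        current_stage = "unifrac"
        distances = {}
        for name, tab in norm.items():
            dm = unifrac_matrix(tab, tree)
            distances[name] = dm
            write_distance_matrix(dm, out / f"unifrac_{name}.tsv")
            record(out / f"unifrac_{name}.tsv")
            log(f"unifrac ({name}): {len(dm.ids)} samples")

        # ------------------------------------------- per-transect ordination,
        # gap-statistic clusters and PERMANOVA on the fly communities
        permanova_rows: list[dict] = []
        cluster_labels: dict[str, pd.Series] = {}
        fly_dm = distances.get("fly")
        transects = (
            sorted(meta.loc[list(fly_dm.ids), "transect"].dropna().unique())
            if fly_dm is not None
            else []
        )
        for transect in transects:
            t_samples = [s for s in fly_dm.ids if meta.at[s, "transect"] == transect]
            if len(t_samples) < 4:
                log(f"{transect}: fewer than 4 samples, skipped")
                continue
            sub_dm = fly_dm.filter(t_samples)

            current_stage = f"pcoa ({transect})"
            ordination = pcoa(sub_dm)
            coords = ordination.coordinates.iloc[:, : min(4, ordination.n_axes)]
            header = (
                "# proportion_explained\t"
                + "\t".join(
                    f"{p:.6f}" for p in ordination.proportion_explained[: coords.shape[1]]
                )
                + "\n"
            )
            p_path = out / f"pcoa_{transect}.tsv"
            with open(p_path, "w", encoding="utf-8") as fh:
                fh.write(header)
                coords.to_csv(fh, sep="\t", float_format="%.10g")
            record(p_path)
            var12 = 100 * ordination.proportion_explained[:2].sum()
            log(f"pcoa ({transect}): axes 1+2 capture {var12:.1f}% of the variance")

            current_stage = f"gap_statistic ({transect})"
            if config.gap_embed == "pcoa":
                points = ordination.coordinates.to_numpy()
            else:
                points = sub_dm.data
            gap = gap_statistic(
                points,
                k_max=min(config.gap_k_max, len(t_samples) - 1),
                b=config.gap_b,
                seed=derive_seed(config.seed, "gap", transect),
            )
            _write_tsv(gap.table, out / f"gap_{transect}.tsv", index=False)
            record(out / f"gap_{transect}.tsv")
            log(f"gap_statistic ({transect}): k_hat = {gap.k_hat} (b = {gap.b})")

            labels, _ = kmeans_cluster(
                points,
                k=gap.k_hat,
                seed=derive_seed(config.seed, "kmeans", transect),
            )
            clusters = pd.Series(
                [f"cluster{c + 1}" for c in labels], index=t_samples, name="cluster"
            )
            cluster_labels[transect] = clusters
            cl = clusters.to_frame()
            cl.index.name = "sample_id"
            _write_tsv(cl, out / f"clusters_{transect}.tsv")
            record(out / f"clusters_{transect}.tsv")

            current_stage = f"permanova ({transect})"
            covariate = TRANSECT_COVARIATE.get(transect)
            tested = [c for c in config.permanova_covariates if c == covariate] or list(
                config.permanova_covariates
            )
            for cov in tested:
                res = permanova(
                    sub_dm,
                    meta.loc[t_samples, cov],
                    n_permutations=config.n_permutations,
                    seed=derive_seed(config.seed, "permanova", transect, cov),
                )
                permanova_rows.append(
                    {
                        "transect": transect,
                        "covariate": cov,
                        "kind": res.kind,
                        "r_squared": res.r_squared,
                        "pseudo_f": res.pseudo_f,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "n_samples": res.n_samples,
                    }
                )
            if clusters.nunique() >= 2:
                res = permanova(
                    sub_dm,
                    clusters,
                    n_permutations=config.n_permutations,
                    seed=derive_seed(config.seed, "permanova", transect, "cluster"),
                )
                permanova_rows.append(
                    {
                        "transect": transect,
                        "covariate": "cluster",
                        "kind": res.kind,
                        "r_squared": res.r_squared,
                        "pseudo_f": res.pseudo_f,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "n_samples": res.n_samples,
                    }
                )
        current_stage = "permanova"
        _write_tsv(pd.DataFrame(permanova_rows), out / "permanova.tsv", index=False)
        record(out / "permanova.tsv")

        # -------------------------------------------------------- composition
        current_stage = "family_composition"
        comp_frames = []
        for stage in sorted({meta.at[s, "stage"] for s in filtered.sample_ids}):
            source = norm.get("pulp" if stage == "pulp" else "fly")
            if source is None:
                continue
            samples = [s for s in source.sample_ids if meta.at[s, "stage"] == stage]
            if not samples:
                continue
            comp = family_composition(
                source.select_samples(samples),
                taxonomy,
                min_mean_abundance=config.family_min_mean_abundance,
            )
            comp.insert(0, "stage", stage)
            comp_frames.append(comp.reset_index())
        _write_tsv(
            pd.concat(comp_frames, ignore_index=True) if comp_frames else pd.DataFrame(),
            out / "family_composition.tsv",
            index=False,
        )
        record(out / "family_composition.tsv")

        # -------------------------------------------------------- associations
        current_stage = "associations"
        assoc_frames = []
        fly_norm = norm.get("fly")
        if fly_norm is not None:
            genus_table = collapse_taxonomy(fly_norm, taxonomy, "genus")
            for transect in transects:
                cov = TRANSECT_COVARIATE[transect]
                for stage in FLY_STAGES:
                    samples = [
                        s
                        for s in genus_table.sample_ids
                        if meta.at[s, "stage"] == stage and meta.at[s, "transect"] == transect
                    ]
                    if len(samples) < 3:
                        continue
                    sub = genus_table.select_samples(samples)
                    res = fit_gradient_models(
                        sub,
                        meta.loc[samples, cov],
                        min_prevalence=config.association_min_prevalence,
                    )
                    res = res.reset_index()
                    res.insert(0, "covariate", cov)
                    res.insert(0, "stage", stage)
                    res.insert(0, "transect", transect)
                    assoc_frames.append(res)
        _write_tsv(
            pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame(),
            out / "associations.tsv",
            index=False,
        )
        record(out / "associations.tsv")
        n_sig = (
            int((pd.concat(assoc_frames)["q_value"] < 0.05).sum()) if assoc_frames else 0
        )
        log(f"associations: {n_sig} (stage, covariate, genus) hits at q < 0.05")

        # -------------------------------------------------------------- lefse
        current_stage = "lefse"
        lefse_frames = []
        if fly_norm is not None:
            genus_table = collapse_taxonomy(fly_norm, taxonomy, "genus")
            for transect, clusters in cluster_labels.items():
                if clusters.nunique() < 2:
                    log(f"lefse ({transect}): single cluster, skipped")
                    continue
                sub = genus_table.select_samples(list(clusters.index))
                try:
                    res = lefse_scores(
                        sub,
                        clusters,
                        alpha=config.lefse_alpha,
                        lda_threshold=config.lefse_lda_threshold,
                        seed=derive_seed(config.seed, "lefse", transect),
                    )
                except ValueError as exc:
                    # e.g. a cluster too small to subsample; report, don't abort
                    log(f"lefse ({transect}): skipped ({exc})")
                    continue
                res = res.reset_index()
                res.insert(0, "transect", transect)
                lefse_frames.append(res)
        _write_tsv(
            pd.concat(lefse_frames, ignore_index=True) if lefse_frames else pd.DataFrame(),
            out / "lefse.tsv",
            index=False,
        )
        record(out / "lefse.tsv")

        # ---------------------------------------------------------------- core
        current_stage = "core_microbiota"
        base_params = CoreParams(
            n_boot=config.core_n_boot,
            subsample_support=config.core_support,
            prevalence_threshold=config.core_prevalence,
            seed=derive_seed(config.seed, "core"),
        )
        pulp_params = CoreParams(
            n_boot=config.core_n_boot,
            subsample_support=config.core_support,
            prevalence_threshold=config.core_prevalence_pulp,
        )
        pieces = [t.data for t in norm.values()]
        combined = FeatureTable(pd.concat(pieces, axis=1)) if pieces else None
        cores = {}
        if combined is not None:
            groups = pd.Series(
                {s: stage_group(meta.at[s, "stage"]) for s in combined.sample_ids},
                name="stage_group",
            )
            cores = group_cores(
                combined,
                meta,
                groups,
                base_params,
                group_params={"pulp": pulp_params},
            )
            for group, result in cores.items():
                _write_tsv(result.summary(), out / f"core_support_{group}.tsv")
                record(out / f"core_support_{group}.tsv")
                log(
                    f"core ({group}): {len(result.core_set)} features at support >= "
                    f"{result.params.subsample_support}, prevalence >= "
                    f"{result.params.prevalence_threshold}"
                )
            regions = core_intersections(cores)
            venn = pd.DataFrame(
                [
                    {"groups": "&".join(k), "n_features": len(v), "features": ",".join(v)}
                    for k, v in sorted(regions.items())
                ]
            )
            _write_tsv(venn, out / "core_venn.tsv", index=False)
            record(out / "core_venn.tsv")

        # ------------------------------------------------------------ manifest
        current_stage = "manifest"
        log_path = out / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        manifest = {p.name: _sha256(p) for p in artifacts}
        manifest["run_log.txt"] = _sha256(log_path)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest

    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage: {current_stage}\nerror: {exc}\n", encoding="utf-8"
        )
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{current_stage}' failed: {exc}") from exc
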
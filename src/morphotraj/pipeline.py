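"""Config-driven end-to-end study runner.

Executes the full inference chain on one or two structures (cranium,
mandible): validation -> missing-landmark estimation -> Procrustes
superimposition (with object symmetry where the template supports it) ->
PCA morphospace (+ plots) -> pooled and per-group allometric regression with
trajectory-angle tests -> group Procrustes distances with permutation tests
on the raw and non-allometric tracks -> rank tests of a chosen PC across
dietary categories -> phylogenetic-signal permutation tests on
size-corrected adult species means.

All randomness flows from one master seed through named per-stage
substreams, recorded in the JSON manifest together with every parameter, so
each stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry as _allometry
from . import groups as _groups
from . import morphospace as _morphospace
from .dataset import LandmarkDataset
from .io import read_landmarks, write_landmarks
from .missing import estimate_missing
from .phylo import bear_tree, phylo_signal_permutation, read_newick
from .procrustes import gpa, gpa_with_object_symmetry
from .simulate import bear_like_params, simulate_ontogeny
from .templates import load_template

logger = logging.getLogger("morphotraj")

__all__ = ["RunConfig", "run_study"]

DIET_MAP = {
    "spelaeus": "herbivore",
    "arctos": "omnivore",
    "americanus": "omnivore",
    "maritimus": "carnivore",
}

# approximate molecular divergence times (Ma) for the study topology;
# overridable in the run config
DIVERGENCE_TIMES_MA = {
    "root": 5.05,
    "spelaeus_split": 2.75,
    "arctos_maritimus": 1.2,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    output_dir: str = "morphotraj_run"
    scenario: str = "bear_like"          # or "null"; ignored when inputs given
    seed: int = 0
    structures: tuple = ("cranium", "mandible")
    input_files: dict = field(default_factory=dict)   # structure -> tps path
    input_format: str = "tps"
    templates: dict = field(
        default_factory=lambda: {"cranium": "cranium36", "mandible": "mandible9"})
    symmetry: dict = field(
        default_factory=lambda: {"cranium": True, "mandible": False})
    n_permutations: int = 10000
    confidence_level: float = 0.95
    diet_map: dict = field(default_factory=lambda: dict(DIET_MAP))
    diet_pc: int = 2                      # 1-based PC used for the rank test
    tree_newick: str | None = None
    divergence_times: dict = field(
        default_factory=lambda: dict(DIVERGENCE_TIMES_MA))
    trajectory_pair: tuple = ("arctos", "spelaeus")
    angle_dimension: int | None = None    # default: effective shape dimension
    scenario_options: dict = field(default_factory=dict)
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be at least 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "structures" in raw:
            raw["structures"] = tuple(raw["structures"])
        if "trajectory_pair" in raw:
            raw["trajectory_pair"] = tuple(raw["trajectory_pair"])
        return cls(**raw)


def _substream(master: int, name: str) -> int:
    """Derive a stable 31-bit stage seed from the master seed and a name."""
    h = np.uint64(1469598103934665603)
    for byte in f"{master}:{name}".encode():
        h = np.uint64((int(h) ^ byte) * 1099511628211 % 2**64)
    return int(h % (2**31 - 1))


def _obtain_dataset(config: RunConfig, structure: str) -> LandmarkDataset:
    template = load_template(config.templates[structure])
    if structure in config.input_files:
        return read_landmarks(
            config.input_files[structure], config.input_format, template)
    if config.scenario not in ("bear_like", "null"):
        raise ValueError(f"unknown scenario {config.scenario!r}")
    params = bear_like_params(
        structure=structure,
        seed=_substream(config.seed, f"simulate:{structure}"),
        null_model=(config.scenario == "null"),
        **config.scenario_options,
    )
    return simulate_ontogeny(params)


def _analyse_structure(config: RunConfig, structure: str, out: Path) -> dict:
    stage_seed = lambda name: _substream(config.seed, f"{name}:{structure}")  # noqa: E731
    logger.info("stage=load structure=%s", structure)
    dataset = _obtain_dataset(config, structure)
    dataset.validate()

    n_incomplete = sum(not s.is_complete for s in dataset)
    if n_incomplete:
        logger.info("stage=estimate_missing structure=%s n=%d",
                    structure, n_incomplete)
        dataset = estimate_missing(dataset)
    write_landmarks(dataset, out / f"{structure}_completed.tps", "tps")

    use_symmetry = config.symmetry.get(structure, False) and \
        dataset.template.has_symmetry
    logger.info("stage=gpa structure=%s symmetry=%s", structure, use_symmetry)
    if use_symmetry:
        gpa_result, sym_result = gpa_with_object_symmetry(dataset)
        coords = sym_result.flattened()
        template = dataset.template
        dimension = _allometry.shape_space_dimension(
            len(dataset), template.n_landmarks, symmetric=True,
            n_paired=len(template.pairs), n_midline=len(template.midline))
    else:
        gpa_result = gpa(dataset)
        coords = gpa_result.flattened()
        dimension = _allometry.shape_space_dimension(
            len(dataset), dataset.template.n_landmarks)
    if config.angle_dimension is not None:
        dimension = config.angle_dimension

    meta = dataset.metadata()
    species = meta["species"].to_numpy()
    age = meta["age_class"].to_numpy()
    group_labels = np.array([f"{s}_{a}" for s, a in zip(species, age)])
    log_sizes = gpa_result.log_centroid_sizes

    logger.info("stage=pca structure=%s", structure)
    pca_raw = _morphospace.pca(coords)
    scores_frame = meta.copy()
    for i in range(min(10, pca_raw.n_components)):
        scores_frame[f"PC{i + 1}"] = pca_raw.scores[:, i]
    scores_frame.to_csv(out / f"{structure}_pc_scores.csv", index=False)

    logger.info("stage=allometry structure=%s", structure)
    pooled = _allometry.regress_shape_on_size(
        coords, log_sizes, n_permutations=config.n_permutations,
        seed=stage_seed("allometry_pooled"))
    nonallo = _allometry.nonallometric_coordinates(pooled)
    pca_nonallo = _morphospace.pca(nonallo)

    pair = tuple(config.trajectory_pair)
    counts = pd.Series(species).value_counts()
    angle_summary = None
    if all(counts.get(p, 0) >= 3 for p in pair):
        mask = np.isin(species, pair)
        regs, angles = _allometry.ontogenetic_trajectories(
            coords[mask], log_sizes[mask], species[mask], pairs=[pair],
            dimension=dimension, n_permutations=config.n_permutations,
            seed=stage_seed("allometry_groups"))
        test = angles[pair]
        angle_summary = {
            "pair": list(pair),
            "angle_degrees": test.angle_degrees,
            "p_value": test.p_value,
            "dimension": test.dimension,
            "percent_predicted": {p: regs[p].percent_predicted for p in pair},
        }

    logger.info("stage=distances structure=%s", structure)
    tables = {}
    for track, data in (("raw", coords), ("nonallometric", nonallo)):
        table = _groups.group_distance_permutation(
            data, group_labels, n_permutations=config.n_permutations,
            seed=stage_seed(f"distances_{track}"), track=track)
        table.to_frame().to_csv(
            out / f"{structure}_distances_{track}.csv", index=False)
        tables[track] = table

    logger.info("stage=rank_tests structure=%s", structure)
    diet = np.array([config.diet_map.get(s, "unknown") for s in species])
    adult = age == "adult"
    pc_idx = config.diet_pc - 1
    kw_values = pca_raw.scores[adult, pc_idx]
    kw_groups = diet[adult]
    kw = _groups.kruskal_wallis(kw_values, kw_groups)
    posthoc = _groups.kruskal_posthoc(kw_values, kw_groups)

    logger.info("stage=phylo structure=%s", structure)
    adult_scores = pca_nonallo.scores[adult]
    adult_species = species[adult]
    tip_values = {
        sp: adult_scores[adult_species == sp].mean(axis=0)
        for sp in np.unique(adult_species)
    }
    if config.tree_newick:
        tree_given = read_newick(config.tree_newick)
        tree_unit = tree_given
    else:
        tree_given = bear_tree("given_lengths", config.divergence_times)
        tree_unit = bear_tree("unit_lengths")
    phylo = {}
    for mode, tree in (("given_lengths", tree_given), ("unit_lengths", tree_unit)):
        result = phylo_signal_permutation(
            tree, tip_values, n_permutations=config.n_permutations,
            seed=stage_seed(f"phylo_{mode}"), branch_mode=mode)
        phylo[mode] = {
            "observed_tree_length": result.observed_tree_length,
            "p_value": result.permutation_p,
            "n_permutations": result.n_permutations,
            "exhaustive": result.exhaustive,
        }

    if config.make_plots:
        _make_plots(structure, pca_raw, group_labels, config, out)

    def _distance_entries(table):
        frame = table.to_frame()
        return [
            {
                "group_a": row.group_a,
                "group_b": row.group_b,
                "distance": float(row.procrustes_distance),
                "p_value": float(row.p_value),
            }
            for row in frame.itertuples()
        ]

    return {
        "structure": structure,
        "n_specimens": len(dataset),
        "n_completed": n_incomplete,
        "symmetry": bool(use_symmetry),
        "gpa_iterations": int(gpa_result.iterations),
        "gpa_converged": bool(gpa_result.converged),
        "shape_dimension": int(dimension),
        "pc_percent_variance": [float(v) for v in pca_raw.percent_variance[:5]],
        "pc1_3_percent": float(pca_raw.percent_variance[:3].sum()),
        "pooled_regression": {
            "percent_predicted": pooled.percent_predicted,
            "permutation_p": pooled.permutation_p,
        },
        "trajectory_angle": angle_summary,
        "distances": {t: _distance_entries(tab) for t, tab in tables.items()},
        "kruskal_wallis": {
            "variable": f"PC{config.diet_pc}",
            "chi_square": kw.chi_square,
            "df": kw.df,
            "p_value": kw.p_value,
            "posthoc_significant_pairs": int(posthoc["significant"].sum()),
            "posthoc_pairs": len(posthoc),
        },
        "phylo_signal": phylo,
    }


def _make_plots(structure: str, pca_result, group_labels, config: RunConfig,
                out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for ci, cj in ((0, 1), (0, 2)):
        if pca_result.n_components <= max(ci, cj):
            continue
        fig, ax = plt.subplots(figsize=(6, 5))
        _morphospace.plot_morphospace(
            pca_result.scores, group_labels, ax=ax, components=(ci, cj),
            level=config.confidence_level,
            percent_variance=pca_result.percent_variance)
        ax.set_title(structure)
        fig.savefig(out / f"{structure}_pc{ci + 1}x{cj + 1}.svg")
        plt.close(fig)
    # wireframe extreme-shape models along the first two PCs
    rows = []
    for comp in range(min(2, pca_result.n_components)):
        lo = float(pca_result.scores[:, comp].min())
        hi = float(pca_result.scores[:, comp].max())
        for tag, score in (("min", lo), ("max", hi)):
            shape = _morphospace.shape_along_pc(pca_result, comp, score)
            for j, (x, y, z) in enumerate(shape, start=1):
                rows.append({
                    "component": comp + 1, "extreme": tag, "score": score,
                    "landmark": j, "x": x, "y": y, "z": z,
                })
    pd.DataFrame(rows).to_csv(
        out / f"{structure}_extreme_shapes.csv", index=False)


def run_study(config: RunConfig) -> dict:
    """Run every stage for every configured structure; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest = {
        "config": {
            key: (list(value) if isinstance(value, tuple) else value)
            for key, value in asdict(config).items()
        },
        "stage_seeds": {},
        "structures": {},
    }
    for structure in config.structures:
        for stage in ("simulate", "allometry_pooled", "allometry_groups",
                      "distances_raw", "distances_nonallometric",
                      "phylo_given_lengths", "phylo_unit_lengths"):
            manifest["stage_seeds"][f"{stage}:{structure}"] = _substream(
                config.seed, f"{stage}:{structure}")
        manifest["structures"][structure] = _analyse_structure(
            config, structure, out)
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info("run complete: %s", out / "manifest.json")
    return manifest
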
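"""End-to-end analysis: ingest -> screen -> GPA -> PCA -> allometry -> signal.

Ventral and dorsal anchors are independent analysis streams that share only
the phylogeny; a species missing one side is dropped from that side only
(its tree tips are pruned for that stream).  Every stage's parameters and
seeds are archived in the run log so a run is reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .allometry import (evolutionary_allometry_test, pic_contrasts,
                        regress_shape_on_size, size_correct)
from .datatypes import LandmarkDataset, Phylogeny
from .errors import DimensionError, MorphosignalError, ValidationError
from .outliers import screen_tangent
from .pca import shape_pca, variance_report
from .procrustes import gpa
from .signal import k_mult, phylomorphospace, tree_length_permutation_test

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_NUMERICAL = 0, 2, 3


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    landmarks: str | None = None          # path to TPS/CSV/XLSX
    tree: str | None = None               # path to Newick, optional
    sides: list[str] = field(default_factory=lambda: ["ventral", "dorsal"])
    scale_policy: str = "ignore"
    outlier_cutoff: float = 0.975
    outlier_per_species: bool = True
    outlier_exclude: bool = True
    pca_top: int = 2
    n_perm_allometry: int = 10_000
    n_perm_tree_length: int = 10_000
    n_rand_kmult: int = 999
    signal_pcs: int | None = None         # None: full tangent data; m: first m PCs
    size_correction: bool = True
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_dataset(config: RunConfig) -> LandmarkDataset:
    path = config.landmarks
    if path is None:
        raise ValidationError("config.landmarks is required")
    suffix = Path(path).suffix.lower()
    if suffix == ".tps":
        return msio.read_tps(path, scale_policy=config.scale_policy)
    return msio.read_table(path)


def _signal_block(values, tree, labels, n_perm, n_rand, seeds) -> dict:
    tl = tree_length_permutation_test(values, tree, n_perm=n_perm,
                                      seed=int(seeds[0]), tip_labels=labels)
    km = k_mult(values, tree, n_rand=n_rand, seed=int(seeds[1]), tip_labels=labels)
    return {
        "tree_length": tl.observed,
        "tree_length_p": tl.p_value,
        "tree_length_permutations": tl.n_permutations,
        "k_mult": km.observed,
        "k_mult_p": km.p_value,
        "k_mult_randomizations": km.n_permutations,
    }


def run_side(
    dataset: LandmarkDataset,
    side: str,
    tree: Phylogeny | None,
    config: RunConfig,
    seeds: np.ndarray,
) -> dict:
    """One anchor side end to end; returns the report dictionary."""
    stream = dataset.filter_side(side)
    report: dict = {"side": side, "n_input": len(stream)}

    if tree is not None:
        tips = set(tree.tip_labels)
        orphans = sorted({s for s in stream.species_ids if s not in tips})
        if orphans:
            raise ValidationError(
                f"{side}: species present in landmarks but absent from tree: {orphans}"
            )
        present = [t for t in tree.tip_labels if t in set(stream.species_ids)]
        side_tree = tree.retain_tips(present) if len(present) < len(tips) else tree
    else:
        side_tree = None

    fit = gpa(stream, scale_policy=config.scale_policy)

    # outlier screen (flag, optionally exclude, then refit)
    screen_note = None
    try:
        reports = screen_tangent(
            fit.tangent, fit.specimen_ids, fit.species_ids,
            per_species=config.outlier_per_species,
            cutoff_prob=config.outlier_cutoff,
        )
        flagged = [sid for r in reports for sid in r.flagged]
    except DimensionError as exc:
        # e.g. a degenerate dataset with no shape variance: nothing to flag
        flagged = []
        screen_note = str(exc)
        logger.warning("%s: outlier screen skipped (%s)", side, exc)
    report["outliers"] = {
        "cutoff_prob": config.outlier_cutoff,
        "per_species": config.outlier_per_species,
        "flagged": flagged,
        "excluded": bool(config.outlier_exclude and flagged),
    }
    if screen_note:
        report["outliers"]["note"] = screen_note
    if config.outlier_exclude and flagged:
        stream = stream.exclude_specimens(flagged)
        fit = gpa(stream, scale_policy=config.scale_policy)
    report["n_analysed"] = len(stream)

    # PCA at both levels
    spec_pca = shape_pca(fit.tangent, level="specimen", row_labels=fit.specimen_ids)
    mean_pca = shape_pca(fit.tangent, level="species_mean",
                         species_ids=fit.species_ids)
    top = min(config.pca_top, mean_pca.n_components)
    report["pca"] = {
        "specimen": variance_report(spec_pca, min(config.pca_top,
                                                  spec_pca.n_components)).to_dict("records"),
        "species_mean": variance_report(mean_pca, top).to_dict("records"),
        "species_mean_cumulative_top2": mean_pca.cumulative_percent(top),
    }

    # allometry and size correction (specimen level)
    allo = regress_shape_on_size(fit.tangent, fit.log_cs,
                                 n_perm=config.n_perm_allometry, seed=int(seeds[0]))
    report["allometry"] = {
        "percent_predicted": allo.percent_predicted,
        "p_value": allo.p_value,
        "n_permutations": allo.n_permutations,
    }
    corrected = size_correct(allo)
    corrected_mean_pca = shape_pca(corrected, level="species_mean",
                                   species_ids=fit.species_ids)
    report["pca"]["species_mean_size_corrected"] = variance_report(
        corrected_mean_pca, min(top, corrected_mean_pca.n_components)
    ).to_dict("records")
    report["pca"]["species_mean_size_corrected_cumulative_top2"] = (
        corrected_mean_pca.cumulative_percent(top)
    )

    bundle_frames = {
        f"pca_species_mean_{side}": variance_report(mean_pca),
        f"pca_species_mean_size_corrected_{side}": variance_report(corrected_mean_pca),
    }

    if side_tree is not None:
        labels, means, mean_logcs = fit.species_means()
        _, corrected_means, _ = _species_means_of(corrected, fit.species_ids)

        # evolutionary allometry on contrasts
        contrasts = pic_contrasts(means, mean_logcs, side_tree, tip_labels=labels)
        evo = evolutionary_allometry_test(contrasts, n_perm=config.n_perm_allometry,
                                          seed=int(seeds[1]))
        report["evolutionary_allometry"] = {
            "percent_predicted": evo.percent_predicted,
            "p_value": evo.p_value,
        }

        def signal_input(matrix):
            if config.signal_pcs is None:
                return matrix
            res = shape_pca(matrix, level="specimen")
            m = min(config.signal_pcs, res.n_components)
            return res.scores[:, :m]

        report["signal"] = {
            "input": ("full tangent data" if config.signal_pcs is None
                      else f"first {config.signal_pcs} PCs"),
            "shape": _signal_block(signal_input(means), side_tree, labels,
                                   config.n_perm_tree_length,
                                   config.n_rand_kmult, seeds[2:4]),
            "size_logcs": _signal_block(mean_logcs.reshape(-1, 1), side_tree, labels,
                                        config.n_perm_tree_length,
                                        config.n_rand_kmult, seeds[6:8]),
        }
        if config.size_correction:
            report["signal"]["shape_size_corrected"] = _signal_block(
                signal_input(corrected_means), side_tree, labels,
                config.n_perm_tree_length, config.n_rand_kmult, seeds[4:6])

        # phylomorphospace node coordinates on the first two PCs
        scores2 = mean_pca.scores[:, : min(2, mean_pca.n_components)]
        nodes, edges, node_labels = phylomorphospace(scores2, side_tree,
                                                     tip_labels=mean_pca.row_labels)
        bundle_frames[f"phylomorphospace_nodes_{side}"] = pd.DataFrame(
            nodes, columns=[f"PC{i + 1}" for i in range(nodes.shape[1])]
        ).assign(label=[l or "" for l in node_labels])
        bundle_frames[f"phylomorphospace_edges_{side}"] = pd.DataFrame(
            edges, columns=["parent", "child"])

    report["_frames"] = bundle_frames
    return report


def _species_means_of(tangent: np.ndarray, species_ids: list[str]):
    order: list[str] = []
    for s in species_ids:
        if s not in order:
            order.append(s)
    means = np.stack([
        tangent[[i for i, sp in enumerate(species_ids) if sp == s]].mean(axis=0)
        for s in order
    ])
    return order, means, None


def run_full(config: RunConfig,
             dataset: LandmarkDataset | None = None,
             tree: Phylogeny | None = None) -> dict:
    """Run every configured anchor side; optionally write the report bundle.

    ``dataset``/``tree`` may be passed in memory (the CLI loads them from
    the configured paths).  Returns a JSON-serializable report dictionary;
    per-side data frames are written as CSV when ``config.outdir`` is set.
    """
    if dataset is None:
        dataset = _load_dataset(config)
    if tree is None and config.tree is not None:
        tree = msio.read_newick(config.tree)

    seeds = np.random.SeedSequence(config.seed).generate_state(64) % (2**31)
    sides_present = sorted(set(dataset.sides))
    sides = [s for s in config.sides if s in sides_present]
    if not sides:
        raise ValidationError(
            f"no configured side present in the data (configured {config.sides}, "
            f"present {sides_present})"
        )

    bundle: dict = {"config": config.to_dict(), "sides": {}}
    frames: dict[str, pd.DataFrame] = {}
    for i, side in enumerate(sides):
        side_report = run_side(dataset, side, tree, config, seeds[8 * i: 8 * (i + 1)])
        frames.update(side_report.pop("_frames"))
        bundle["sides"][side] = side_report

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        index = {"report": "report.json", "tables": {}}
        for name, frame in frames.items():
            fname = f"{name}.csv"
            frame.to_csv(outdir / fname, index=False)
            index["tables"][name] = fname
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, default=_json_default), encoding="utf-8")
        (outdir / "index.json").write_text(json.dumps(index, indent=2),
                                           encoding="utf-8")
        logger.info("report bundle written to %s", outdir)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
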
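"""End-to-end cranial disparity workflow.

Per view: parse TPS + sliders + specimen table, reflect left-side specimens,
run generalized Procrustes alignment with sliding semilandmarks, average
aligned specimens into species means, run tangent-space PCA, select the axes
carrying 95% of the variance, compute per-family disparity (mean Euclidean
distance to the family centroid), and compare families with a Welch t test on
the per-species distances, a label-shuffling permutation test on the
disparity difference, and a PERMANOVA on morphospace positions.

An optional subset re-analysis drops part of an over-represented genus and
repeats the ENTIRE pipeline from the Procrustes alignment onward — not just
a filtering of scores — because removing specimens changes the consensus,
the tangent space and every downstream statistic.

Outputs are CSV-only (disparity table, permutation table, PERMANOVA summary,
scores, eigenvalue summary, aligned coordinates, PC1-2 scatter data) plus a
JSON-lines run log recording every parameter and seed. Re-running with the
same inputs and seeds is bit-reproducible at the CSV level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .align import AlignedSet, gpa_align, species_means
from .disparity import DisparityResult, disparity_table
from .inference import (NpManovaResult, PermutationResult, np_manova,
                        permutation_disparity_test, welch_t)
from .ordination import TangentSpace, tangent_pca
from .tps import (LandmarkConfiguration, parse_sliders, parse_tps, reflect,
                  read_specimen_table)

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "ViewResult", "load_dataset", "subset_species",
           "run_view", "run_analysis"]


@dataclasses.dataclass
class Dataset:
    """Configurations plus slider triples and the specimen table."""

    configs: list[LandmarkConfiguration]
    sliders: list
    table: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(c.species for c in self.configs))


@dataclasses.dataclass
class ViewResult:
    """All intermediate and final results for one view's analysis."""

    view: str
    aligned: AlignedSet
    species_set: object
    tangent: TangentSpace
    retained: int
    disparity_first: DisparityResult
    disparity_second: DisparityResult
    difference: float
    welch: tuple[float, float, float]  # t, df, p
    permutation: PermutationResult
    manova: NpManovaResult


def load_dataset(tps_path, sliders_path, table_path) -> Dataset:
    """Load a TPS file, sliders file and specimen table from disk."""
    table = read_specimen_table(table_path)
    with open(tps_path) as fh:
        configs = parse_tps(fh, table)
    if not configs:
        raise ValueError(f"no TPS records in {tps_path}")
    with open(sliders_path) as fh:
        sliders = parse_sliders(fh, configs[0].fixed_count, configs[0].n_points)
    return Dataset(configs=configs, sliders=sliders, table=table)


def subset_species(dataset: Dataset, keep_list) -> Dataset:
    """Thin over-represented genera down to the species in ``keep_list``.

    Every species named in ``keep_list`` must be present. Species belonging
    to the same genus (leading underscore-delimited token of the species
    name) as any kept species are dropped unless they are themselves kept;
    species of unrelated genera are all retained. With ``keep_list`` equal to
    all species this is the identity.
    """
    present = set(dataset.species)
    keep = set(keep_list)
    unknown = keep - present
    if unknown:
        raise ValueError(f"unknown species in keep list: {sorted(unknown)}")
    target_genera = {sp.split("_")[0] for sp in keep}
    kept = {
        sp for sp in present
        if sp in keep or sp.split("_")[0] not in target_genera
    }
    configs = [c for c in dataset.configs if c.species in kept]
    table = dataset.table[dataset.table["species"].isin(kept)].reset_index(drop=True)
    logger.info("subset: kept %d of %d species (%d specimens)",
                len(kept), len(present), len(configs))
    return Dataset(configs=configs, sliders=dataset.sliders, table=table)


def run_view(dataset: Dataset, axis_threshold: float = 0.95,
             n_perm_disparity: int = 1000, n_perm_manova: int = 999,
             seed: int | None = None, family_order: list[str] | None = None,
             tol: float = 1e-8, max_iter: int = 100) -> ViewResult:
    """Run the full analysis on one view's dataset."""
    views = {c.view for c in dataset.configs}
    if len(views) != 1:
        raise ValueError(f"dataset mixes views: {sorted(views)}")
    view = views.pop()
    side = dataset.table.set_index("specimen_id").get("side")
    configs = []
    for c in dataset.configs:
        if side is not None and str(side.get(c.specimen_id, "right")) == "left":
            c = reflect(c)
        configs.append(c)
    aligned = gpa_align(configs, dataset.sliders, tol=tol, max_iter=max_iter)
    sp_means = species_means(aligned, dataset.table)
    tangent = tangent_pca(sp_means, threshold=axis_threshold)
    # a dataset with no real shape variation leaves only numerical noise in
    # the scores; zero it so downstream statistics degrade gracefully
    ref_scale = float((sp_means.flattened() ** 2).sum(axis=1).mean())
    if tangent.eigenvalues.sum() < 1e-15 * max(ref_scale, 1e-300):
        tangent = dataclasses.replace(
            tangent, scores=np.zeros_like(tangent.scores), retained=1)
    m = tangent.retained
    first, second, diff = disparity_table(
        tangent.scores, tangent.family, m=m, family_order=family_order)
    try:
        t, df, p_t = welch_t(first.distances, second.distances)
    except ValueError:  # both families dispersion-free
        t = df = p_t = float("nan")
        logger.warning("Welch t undefined: zero variance in both families")
    perm = permutation_disparity_test(
        tangent.scores, tangent.family, m=m, n_perm=n_perm_disparity,
        seed=seed, family_order=family_order)
    manova_seed = None if seed is None else seed + 1
    try:
        manova = np_manova(tangent.scores, tangent.family, m=m,
                           n_perm=n_perm_manova, seed=manova_seed)
    except ValueError:  # all morphospace positions identical
        logger.warning("PERMANOVA skipped: degenerate data")
        manova = NpManovaResult(
            pseudo_F=float("nan"), r_squared=float("nan"), p_value=float("nan"),
            df_between=len(set(tangent.family)) - 1,
            df_within=len(tangent.family) - len(set(tangent.family)),
            n_perm=n_perm_manova, seed=manova_seed)
    return ViewResult(
        view=view, aligned=aligned, species_set=sp_means, tangent=tangent,
        retained=m, disparity_first=first, disparity_second=second,
        difference=diff, welch=(t, df, p_t), permutation=perm, manova=manova,
    )


# ---------------------------------------------------------------------------
# CSV serialization


def _disparity_frame(res: ViewResult) -> pd.DataFrame:
    t, df, p = res.welch
    return pd.DataFrame({
        "family": [res.disparity_first.family, res.disparity_second.family],
        "n": [res.disparity_first.n, res.disparity_second.n],
        "disparity_mean": [res.disparity_first.mean, res.disparity_second.mean],
        "disparity_se": [res.disparity_first.se, res.disparity_second.se],
        "welch_t": [t, np.nan],
        "welch_df": [df, np.nan],
        "welch_p": [p, np.nan],
    })


def _permutation_frame(res: ViewResult) -> pd.DataFrame:
    return pd.DataFrame({
        "disparity_first": [res.disparity_first.mean],
        "disparity_second": [res.disparity_second.mean],
        "difference": [res.permutation.observed_difference],
        "null_min": [res.permutation.null_min],
        "null_max": [res.permutation.null_max],
        "p_value": [res.permutation.p_value],
        "n_perm": [res.permutation.n_perm],
    })


def _manova_frame(res: ViewResult) -> pd.DataFrame:
    m = res.manova
    return pd.DataFrame({
        "pseudo_F": [m.pseudo_F], "r_squared": [m.r_squared],
        "p_value": [m.p_value], "df_between": [m.df_between],
        "df_within": [m.df_within], "n_perm": [m.n_perm],
    })


def _scores_frame(res: ViewResult) -> pd.DataFrame:
    cols = {f"PC{i + 1}": res.tangent.scores[:, i]
            for i in range(res.tangent.scores.shape[1])}
    return pd.DataFrame({"species": res.tangent.species,
                         "family": res.tangent.family, **cols})


def _eigen_frame(res: ViewResult) -> pd.DataFrame:
    return pd.DataFrame({
        "axis": [f"PC{i + 1}" for i in range(len(res.tangent.eigenvalues))],
        "eigenvalue": res.tangent.eigenvalues,
        "proportion": res.tangent.proportions,
        "cumulative": np.cumsum(res.tangent.proportions),
    })


def _aligned_frame(res: ViewResult) -> pd.DataFrame:
    n, k, _ = res.aligned.coordinates.shape
    flat = res.aligned.coordinates.reshape(n, 2 * k)
    cols = {}
    for i in range(k):
        cols[f"x{i + 1}"] = flat[:, 2 * i]
        cols[f"y{i + 1}"] = flat[:, 2 * i + 1]
    return pd.DataFrame({"specimen_id": res.aligned.specimen_ids,
                         "centroid_size": res.aligned.centroid_sizes, **cols})


def write_view_result(res: ViewResult, out_dir, prefix: str = "") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = f"{prefix}{res.view}"
    paths = {}
    for stem, frame in [
        ("disparity", _disparity_frame(res)),
        ("permutation", _permutation_frame(res)),
        ("npmanova", _manova_frame(res)),
        ("scores", _scores_frame(res)),
        ("eigen", _eigen_frame(res)),
        ("aligned", _aligned_frame(res)),
    ]:
        path = out / f"{name}_{stem}.csv"
        frame.to_csv(path, index=False)
        paths[stem] = path
    scatter = _scores_frame(res).iloc[:, :4]  # species, family, PC1, PC2
    path = out / f"{name}_pc12.csv"
    scatter.to_csv(path, index=False)
    paths["pc12"] = path
    return paths


# ---------------------------------------------------------------------------


def run_analysis(run_config) -> dict[str, ViewResult]:
    """Run the configured workflow; write CSVs and a JSON-lines log.

    ``run_config`` is a YAML path or a dict with keys::

        views: {dorsal: {tps: ..., sliders: ...}, ...}
        table: specimens.csv
        out_dir: results/
        families: [FamilyA, FamilyB]      # optional order of comparison
        axis_threshold: 0.95
        n_perm_disparity: 1000
        n_perm_manova: 999
        seed: 42
        subset_keep: [SpeciesA, ...]      # optional subset re-analysis
        tol: 1.0e-8
        max_iter: 100

    Analyses run independently per view. The subset, when requested, re-runs
    the whole pipeline from alignment onward with a ``subset_`` CSV prefix.
    """
    if not isinstance(run_config, dict):
        with open(run_config) as fh:
            run_config = yaml.safe_load(fh)
    cfg = dict(run_config)
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    results: dict[str, ViewResult] = {}
    common = dict(
        axis_threshold=float(cfg.get("axis_threshold", 0.95)),
        n_perm_disparity=int(cfg.get("n_perm_disparity", 1000)),
        n_perm_manova=int(cfg.get("n_perm_manova", 999)),
        seed=cfg.get("seed"),
        family_order=cfg.get("families"),
        tol=float(cfg.get("tol", 1e-8)),
        max_iter=int(cfg.get("max_iter", 100)),
    )
    with open(log_path, "w") as log:
        def emit(stage, **kw):
            log.write(json.dumps({"stage": stage, **kw}, default=str) + "\n")

        emit("config", **{k: str(v) for k, v in cfg.items()})
        for view, paths in cfg["views"].items():
            dataset = load_dataset(paths["tps"], paths["sliders"], cfg["table"])
            emit("loaded", view=view, n_specimens=len(dataset.configs),
                 n_species=len(dataset.species))
            res = run_view(dataset, **common)
            write_view_result(res, out_dir)
            emit("analysed", view=view, retained_axes=res.retained,
                 iterations=res.aligned.iterations_run,
                 converged=res.aligned.converged,
                 difference=res.difference,
                 permutation_p=res.permutation.p_value,
                 npmanova_p=res.manova.p_value, seed=common["seed"])
            results[view] = res
            if cfg.get("subset_keep"):
                sub = subset_species(dataset, cfg["subset_keep"])
                emit("subset", view=view, n_specimens=len(sub.configs),
                     n_species=len(sub.species))
                sub_res = run_view(sub, **common)
                write_view_result(sub_res, out_dir, prefix="subset_")
                emit("analysed_subset", view=view,
                     retained_axes=sub_res.retained,
                     difference=sub_res.difference,
                     permutation_p=sub_res.permutation.p_value,
                     npmanova_p=sub_res.manova.p_value)
                results[f"subset_{view}"] = sub_res
    return results
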
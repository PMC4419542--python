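"""Synthetic skull-landmark datasets with known truth.

The generator emulates the statistical structure a cranial disparity analysis
assumes, so every pipeline stage can be tested without museum specimens:

* two families with distinct mean shapes (so a multivariate location test
  separates them),
* species-level shape dispersion controlling the true within-family
  disparity, optionally with an over-sampled low-variance species cluster
  (emulating a speciose shrew-like genus that can mask family-level
  disparity),
* specimen-level digitization noise, and
* an arbitrary rigid rotation/translation/pixel-scale per specimen, with a
  fraction of specimens emitted mirrored as if photographed from the left.

Shape variation lives in a three-parameter deformation space — rostral
elongation, cranial width and braincase doming — applied to a smooth
parametric skull template (superellipse braincase plus a tapering rostrum),
rather than as independent per-landmark noise. This concentrates variance on
a few principal axes, as in real cranial data; isotropic digitization noise
supplies the remainder. Curves are densely sampled and resampled to the
per-view semilandmark counts: dorsal 10 landmarks + 44 semilandmarks over 4
curves, ventral 13 + 60, lateral 9 + 35 over 2 curves.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .outlines import resample_curve
from .tps import LandmarkConfiguration, SliderTriple, write_sliders, write_tps

__all__ = [
    "FamilySpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "make_template",
    "generate_dataset",
    "masking_scenario",
    "default_config",
]

# millimetres per template unit: a unit-braincase skull spans roughly 30 mm
TEMPLATE_MM = 15.0

#: per-view structure: (fixed landmarks, semilandmarks per curve)
VIEW_STRUCTURE = {
    "dorsal": (10, (11, 11, 11, 11)),
    "ventral": (13, (15, 15, 15, 15)),
    "lateral": (9, (18, 17)),
}

#: neutral deformation parameters (rostral elongation, cranial width, doming)
NEUTRAL_PARAMS = np.array([0.7, 0.65, 0.45])


# ---------------------------------------------------------------------------
# parametric skull geometry


def _superellipse_upper(omega: float, p: float, x: np.ndarray) -> np.ndarray:
    """y >= 0 branch of |x|^p + |y/omega|^p = 1 evaluated at x in [-1, 1]."""
    return omega * np.maximum(1.0 - np.abs(x) ** p, 0.0) ** (1.0 / p)


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _braincase_arc(omega: float, p: float, x0: float, x1: float, n: int) -> np.ndarray:
    x = np.linspace(x0, x1, n)
    return np.column_stack([x, _superellipse_upper(omega, p, x)])


def _top_view_geometry(params, dense: int = 400):
    """Fixed landmarks and dense outline curves for dorsal/ventral silhouettes."""
    rho, omega, delta = params
    p_exp = 1.6 + 0.8 * delta
    xs = 0.6  # snout-base x on the braincase
    ws = _superellipse_upper(omega, p_exp, np.array([xs]))[0]
    tip = np.array([xs + rho, 0.0])
    # right side: posterior pole -> widest point -> snout base -> tip
    post_arc = _braincase_arc(omega, p_exp, -1.0, 0.0, dense)  # LM pole -> widest
    ant_arc = _braincase_arc(omega, p_exp, 0.0, xs, dense)  # widest -> snout base
    snout = _bezier([xs, ws], [xs + 0.65 * rho, 0.55 * ws], tip, dense)
    right_anterior = np.vstack([ant_arc, snout[1:]])
    mirror = np.array([1.0, -1.0])
    curves = [
        post_arc,  # posterior pole -> right widest
        right_anterior,  # right widest -> tip
        post_arc * mirror,  # posterior pole -> left widest
        right_anterior * mirror,  # left widest -> tip
    ]
    fixed = {
        "pole": np.array([-1.0, 0.0]),
        "tip": tip,
        "widest_r": np.array([0.0, omega]),
        "widest_l": np.array([0.0, -omega]),
        "snout_r": np.array([xs, ws]),
        "snout_l": np.array([xs, -ws]),
    }
    return fixed, curves, dict(xs=xs, ws=ws, omega=omega, p_exp=p_exp)


def _dorsal_template(params, dense: int = 400):
    rho, omega, delta = params
    fixed, curves, aux = _top_view_geometry(params, dense)
    orbit_y = 0.45 * omega * (0.8 + 0.4 * delta)
    lms = [
        fixed["pole"], fixed["tip"], fixed["widest_r"], fixed["widest_l"],
        fixed["snout_r"], fixed["snout_l"],
        np.array([0.35, orbit_y]), np.array([0.35, -orbit_y]),
        np.array([-0.6, 0.35 * omega]), np.array([-0.6, -0.35 * omega]),
    ]
    attach = [(0, 2), (2, 1), (0, 3), (3, 1)]  # (start LM, end LM) per curve
    return np.array(lms), curves, attach


def _ventral_template(params, dense: int = 400):
    rho, omega, delta = params
    fixed, curves, aux = _top_view_geometry((rho, omega, 0.8 * delta), dense)
    ws = aux["ws"]
    lms = [
        fixed["pole"], fixed["tip"], fixed["widest_r"], fixed["widest_l"],
        fixed["snout_r"], fixed["snout_l"],
        np.array([0.3, 0.0]),                       # mid palate
        np.array([aux["xs"] + 0.6 * rho, 0.0]),     # anterior palate
        np.array([0.45, 0.55 * ws]), np.array([0.45, -0.55 * ws]),   # tooth rows
        np.array([-0.55, 0.5 * omega]), np.array([-0.55, -0.5 * omega]),  # bullae
        np.array([-0.75, 0.0]),                     # foramen magnum
    ]
    attach = [(0, 2), (2, 1), (0, 3), (3, 1)]
    return np.array(lms), curves, attach


def _lateral_template(params, dense: int = 400):
    rho, omega, delta = params
    xs = 0.6
    tip_x = xs + rho
    h = 0.45 + 0.5 * delta  # dome height above the base line
    base = 0.06

    def dorsal_profile(x):
        return base + h * np.exp(-(((x + 0.2) / 0.55) ** 2))

    def ventral_profile(x):
        u = np.clip((x + 0.1) / (tip_x + 0.95), -1.0, 1.0)
        return -0.05 - 0.12 * (1.0 - u**2) - 0.02 * omega

    post_dorsal = np.array([-1.0, dorsal_profile(-1.0)])
    tip = np.array([tip_x, base])
    post_ventral = np.array([-1.0, ventral_profile(-1.0)])
    xd = np.linspace(-1.0, tip_x, dense)
    dorsal_curve = np.column_stack([xd, dorsal_profile(xd)])
    dorsal_curve[-1] = tip
    xv = np.linspace(tip_x, -1.0, dense)
    ventral_curve = np.column_stack([xv, ventral_profile(xv)])
    ventral_curve[0] = tip
    lms = [
        post_dorsal, tip, post_ventral,
        np.array([0.25, 0.25 * h]),                  # orbit
        np.array([-0.5, -0.1 - 0.05 * omega]),       # auditory bulla
        np.array([xs + 0.7 * rho, -0.06]),           # anterior tooth row
        np.array([0.3, -0.1]),                       # posterior tooth row
        np.array([-0.2, base + h]),                  # braincase apex
        np.array([-0.95, -0.05]),                    # occipital condyle
    ]
    attach = [(0, 1), (1, 2)]
    return np.array(lms), [dorsal_curve, ventral_curve], attach


_VIEW_GEOMETRY = {
    "dorsal": _dorsal_template,
    "ventral": _ventral_template,
    "lateral": _lateral_template,
}


def template_points(view: str, params=NEUTRAL_PARAMS) -> np.ndarray:
    """Landmark + semilandmark coordinates (mm) for a view and shape params."""
    if view not in _VIEW_GEOMETRY:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(_VIEW_GEOMETRY)}")
    fixed_count, per_curve = VIEW_STRUCTURE[view]
    lms, dense_curves, _ = _VIEW_GEOMETRY[view](np.asarray(params, dtype=float))
    parts = [lms]
    for dense, n_semi in zip(dense_curves, per_curve):
        # endpoints are anchored at fixed landmarks; semilandmarks are the
        # interior equally spaced points
        pts = resample_curve(dense, n_semi + 2)[1:-1]
        parts.append(pts)
    return np.vstack(parts) * TEMPLATE_MM


def make_template(view: str, params=NEUTRAL_PARAMS,
                  ) -> tuple[LandmarkConfiguration, list[SliderTriple]]:
    """Skull-like template configuration and its paired slider triples.

    Each curve runs between two fixed landmarks; its semilandmarks are the
    equally spaced interior points. Every semilandmark receives a
    before/slide/after triple whose outer members are either its curve
    neighbours or the adjacent fixed landmark at the curve ends.
    """
    if view not in VIEW_STRUCTURE:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_STRUCTURE)}")
    fixed_count, per_curve = VIEW_STRUCTURE[view]
    _, _, attach = _VIEW_GEOMETRY[view](np.asarray(params, dtype=float))
    points = template_points(view, params)
    curves = []
    start = fixed_count
    for n_semi in per_curve:
        curves.append((start, start + n_semi))
        start += n_semi
    config = LandmarkConfiguration(
        specimen_id="template",
        species="template",
        family="template",
        view=view,
        points=points,
        fixed_count=fixed_count,
        curves=curves,
        scale_applied=True,
    )
    triples = []
    for (start, stop), (lm_start, lm_end) in zip(curves, attach):
        idx = list(range(start, stop))
        neighbours = [lm_start] + idx + [lm_end]
        for j, slider in enumerate(idx, start=1):
            triples.append(SliderTriple(neighbours[j - 1], slider, neighbours[j + 1]))
    return config, triples


# ---------------------------------------------------------------------------
# hierarchical sampling


@dataclasses.dataclass
class FamilySpec:
    """One family's sampling parameters.

    ``mean_params`` are the family-mean deformation parameters (rostral
    elongation, cranial width, braincase doming); ``species_sd`` is the
    between-species dispersion in that parameter space — the truth underlying
    the family's disparity. An optional cluster of ``n_cluster_species``
    species is drawn around ``mean_params + cluster_offset`` with the much
    smaller ``cluster_sd``, emulating an over-sampled low-variance genus.
    ``cluster_genus`` names the genus label given to cluster species.
    """

    name: str
    n_species: int
    mean_params: tuple[float, float, float]
    species_sd: float
    n_cluster_species: int = 0
    cluster_sd: float = 0.0
    cluster_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    genus: str = ""
    cluster_genus: str = "Cluster"

    def __post_init__(self):
        if self.n_species <= 0:
            raise ValueError("n_species must be positive")
        if not 0 <= self.n_cluster_species <= self.n_species:
            raise ValueError("n_cluster_species must be in [0, n_species]")
        if self.species_sd < 0 or self.cluster_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if not self.genus:
            self.genus = self.name[:7]


@dataclasses.dataclass
class SyntheticConfig:
    """Study-design parameters for a synthetic dataset.

    Defaults echo the study frame of a tenrec-vs-golden-mole comparison: a
    31-species family containing a 19-species low-variance cluster versus a
    12-species family, with uneven specimen sampling per species (uniform
    1..21), sub-pixel-scale digitization noise, and arbitrary
    rotation/translation/pixel-scale nuisance per photographed specimen.
    """

    seed: int
    view: str = "dorsal"
    families: Sequence[FamilySpec] = ()
    specimens_per_species: int | tuple[int, int] = (1, 21)
    digitization_sd: float = 0.1  # mm
    size_jitter_sd: float = 0.05  # lognormal sd of per-specimen size factor
    rotation_range: tuple[float, float] = (-np.pi, np.pi)
    translation_range: float = 15.0  # mm
    pixel_scale_range: tuple[float, float] = (0.02, 0.05)  # mm per pixel
    left_side_fraction: float = 0.25

    def __post_init__(self):
        if self.view not in VIEW_STRUCTURE:
            raise ValueError(f"unknown view {self.view!r}")
        if self.digitization_sd < 0:
            raise ValueError("digitization_sd must be non-negative")
        if not 0.0 <= self.left_side_fraction <= 1.0:
            raise ValueError("left_side_fraction must be in [0, 1]")
        if not self.families:
            raise ValueError("at least one family spec required")


@dataclasses.dataclass
class SyntheticDataset:
    """Generated configurations plus sliders, specimen table and truth."""

    configs: list[LandmarkConfiguration]
    sliders: list[SliderTriple]
    table: pd.DataFrame
    truth: dict
    pixel_scales: np.ndarray | None = None

    def write(self, out_dir) -> None:
        """Write landmarks.tps (pixel units + SCALE), sliders, table, truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "landmarks.tps", "w") as fh:
            write_tps(self.configs, fh, scales=self.pixel_scales)
        with open(out / "sliders.txt", "w") as fh:
            write_sliders(self.sliders, fh)
        self.table.to_csv(out / "specimens.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _preshape_flat(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    return (c / np.sqrt((c**2).sum())).ravel()


def _species_params(spec: FamilySpec, rng: np.random.Generator):
    """Latent per-species parameters and labels for one family."""
    mean = np.asarray(spec.mean_params, dtype=float)
    offset = np.asarray(spec.cluster_offset, dtype=float)
    names, params, clustered = [], [], []
    n_regular = spec.n_species - spec.n_cluster_species
    for j in range(n_regular):
        names.append(f"{spec.genus}_sp{j + 1:02d}")
        params.append(mean + rng.normal(0.0, spec.species_sd, size=3))
        clustered.append(False)
    for j in range(spec.n_cluster_species):
        names.append(f"{spec.cluster_genus}_sp{j + 1:02d}")
        params.append(mean + offset + rng.normal(0.0, spec.cluster_sd, size=3))
        clustered.append(True)
    return names, np.array(params), clustered


def _true_dispersion(view: str, params: np.ndarray) -> float:
    """Noiseless shape-space disparity of a set of species parameter points."""
    shapes = np.stack([_preshape_flat(template_points(view, p)) for p in params])
    centroid = shapes.mean(axis=0)
    return float(np.linalg.norm(shapes - centroid, axis=1).mean())


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset, reproducible from ``config.seed``.

    Hierarchical model: species mean parameters = family mean + Gaussian
    species effect; specimen landmarks = species template + isotropic
    digitization noise (mm) + random similarity transform into pixel
    coordinates (recorded in the TPS SCALE field). A ``left_side_fraction``
    of specimens is emitted mirrored, flagged ``side=left`` in the table.
    """
    rng = np.random.default_rng(config.seed)
    template_cfg, sliders = make_template(config.view)
    fixed_count, _ = VIEW_STRUCTURE[config.view]

    configs: list[LandmarkConfiguration] = []
    rows = []
    pixel_scales: list[float] = []
    truth: dict = {"seed": config.seed, "view": config.view, "families": {}}
    for spec in config.families:
        names, params, clustered = _species_params(spec, rng)
        truth["families"][spec.name] = {
            "mean_params": list(spec.mean_params),
            "species_sd": spec.species_sd,
            "species": {
                nm: {"params": p.tolist(), "clustered": cl}
                for nm, p, cl in zip(names, params, clustered)
            },
            "true_dispersion": _true_dispersion(config.view, params),
        }
        for nm, p in zip(names, params):
            species_mm = template_points(config.view, p)
            if isinstance(config.specimens_per_species, int):
                n_spec = config.specimens_per_species
            else:
                lo, hi = config.specimens_per_species
                n_spec = int(rng.integers(lo, hi + 1))
            for r in range(n_spec):
                sid = f"{nm}_{r + 1:02d}"
                pts = species_mm + rng.normal(0.0, config.digitization_sd,
                                              size=species_mm.shape)
                side = "left" if rng.random() < config.left_side_fraction else "right"
                if side == "left":
                    pts = pts * np.array([-1.0, 1.0])  # mirrored photograph
                theta = rng.uniform(*config.rotation_range)
                c, s = np.cos(theta), np.sin(theta)
                pts = pts @ np.array([[c, s], [-s, c]])
                pts = pts * rng.lognormal(0.0, config.size_jitter_sd)
                pts = pts + rng.uniform(0.0, config.translation_range, size=2)
                pixel_scales.append(rng.uniform(*config.pixel_scale_range))
                configs.append(LandmarkConfiguration(
                    specimen_id=sid,
                    species=nm,
                    family=spec.name,
                    view=config.view,
                    points=pts,
                    fixed_count=fixed_count,
                    curves=list(template_cfg.curves),
                    scale_applied=True,
                ))
                rows.append({
                    "specimen_id": sid, "species": nm, "family": spec.name,
                    "view": config.view, "side": side,
                })
    if len(truth["families"]) >= 2:
        fams = list(truth["families"].values())
        d0, d1 = fams[0]["true_dispersion"], fams[1]["true_dispersion"]
        truth["dispersion_ratio"] = d0 / d1 if d1 > 0 else np.inf
    table = pd.DataFrame(rows)
    return SyntheticDataset(configs=configs, sliders=sliders, table=table,
                            truth=truth, pixel_scales=np.array(pixel_scales))


def masking_scenario(config: SyntheticConfig, n_keep: int = 5,
                     ) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Full dataset plus a cluster-thinned subset for the masking contrast.

    The full dataset contains the over-sampled low-variance cluster; the
    subset retains ``n_keep`` cluster species (evenly spaced across the
    cluster, mimicking one representative per sub-division) together with all
    non-cluster species of that family and every species of any other
    family. Both datasets share the same draw: the subset is a pure
    filtering of the full one.
    """
    cluster_specs = [f for f in config.families if f.n_cluster_species > 0]
    if not cluster_specs:
        raise ValueError("masking scenario requires a family with a cluster spec")
    for f in cluster_specs:
        if n_keep > f.n_cluster_species:
            raise ValueError(
                f"subset of {n_keep} exceeds cluster size {f.n_cluster_species}"
            )
    full = generate_dataset(config)
    keep: set[str] = set()
    for spec in config.families:
        fam_species = [nm for nm in full.truth["families"][spec.name]["species"]]
        cluster = [nm for nm in fam_species
                   if full.truth["families"][spec.name]["species"][nm]["clustered"]]
        non_cluster = [nm for nm in fam_species if nm not in cluster]
        keep.update(non_cluster)
        if cluster:
            pick = np.unique(np.linspace(0, len(cluster) - 1, n_keep).round().astype(int))
            keep.update(cluster[i] for i in pick)
    mask = np.array([c.species in keep for c in full.configs])
    sub_configs = [c for c, k in zip(full.configs, mask) if k]
    sub_table = full.table[full.table["species"].isin(keep)].reset_index(drop=True)
    subset = SyntheticDataset(
        configs=sub_configs,
        sliders=full.sliders,
        table=sub_table,
        truth={**full.truth, "subset_of": config.seed,
               "kept_species": sorted(keep)},
        pixel_scales=None if full.pixel_scales is None else full.pixel_scales[mask],
    )
    return full, subset


def default_config(seed: int, view: str = "dorsal", **overrides) -> SyntheticConfig:
    """The documented study-frame defaults (see class docstrings)."""
    families = (
        FamilySpec(
            name="Tenrecidae", genus="Tenrec", n_species=31,
            mean_params=(0.9, 0.55, 0.35), species_sd=0.05,
            n_cluster_species=19, cluster_sd=0.012,
            cluster_offset=(0.08, -0.03, -0.02), cluster_genus="Microgale",
        ),
        FamilySpec(
            name="Chrysochloridae", genus="Chrysoc", n_species=12,
            mean_params=(0.78, 0.61, 0.41), species_sd=0.05,
        ),
    )
    kwargs = dict(seed=seed, view=view, families=families)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)
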
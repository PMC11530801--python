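"""Seeded generator of synthetic worm FLIM stacks with ground-truth labels.

The generator emulates the statistical structure of BODIPY vital-stained
*C. elegans* intestinal FLIM images that the downstream analysis assumes:

* an elliptical worm-body region;
* two organelle classes with distinct decay physics — lysosome-related
  organelles (LROs; narrow monoexponential decay at 1.5 ns) and lipid
  droplets (LDs; broad two-component decay calibrated so the class-level
  FLF loss is 58.3%);
* diffuse short-lifetime (1.0 ns) autofluorescence, plus discrete
  autofluorescent granules in aged unstained worms;
* dye-concentration-dependent brightness — LD brightness grows linearly with
  BODIPY concentration while LRO brightness grows like its square root, so
  the LD:LRO intensity ratio improves at high concentration;
* per-organelle log-normal brightness heterogeneity, so "ten brightest"
  ROI selection is meaningful.

Everything is deterministic for a fixed config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .decay import (
    DecayModel,
    default_bin_edges,
    autofluorescence_model,
    ld_model,
    lro_model,
    sample_arrival_times,
)

logger = logging.getLogger(__name__)

#: BODIPY staining concentrations used in the concentration study (uM).
CONCENTRATION_PANEL_UM = (1.0, 4.0, 8.0, 12.0)

#: Wild-type default LD radius mean (px); enlarged-LD mutants scale this.
WT_LD_RADIUS_MEAN = 3.0


class OrganelleClass(str, Enum):
    LD = "LD"
    LRO = "LRO"
    AUTOFLUORESCENCE = "autofluorescence"


class Genotype(str, Enum):
    WT = "WT"
    GLO1 = "glo1"                    # lacks LROs
    DAF22 = "daf22"                  # enlarged LDs
    DAF2_HIGHFAT = "daf2_highfat"    # high-fat phenotype
    HB101_LOWFAT = "hb101_lowfat"    # low-fat phenotype (HB101 diet)
    UNSTAINED_AGED = "unstained_aged"  # autofluorescence only


class WormConfig(BaseModel):
    """Ground-truth description of one synthetic worm scene."""

    model_config = {"frozen": True}

    genotype: Genotype = Genotype.WT
    concentration: float = 1.0          # BODIPY concentration, uM
    image_shape: tuple[int, int] = (128, 128)
    n_LD: int = 12
    n_LRO: int = 12
    n_auto_granules: int = 0
    LD_radius: tuple[float, float] = (WT_LD_RADIUS_MEAN, 0.8)   # (mean, sd) px
    LRO_radius: tuple[float, float] = (2.0, 0.5)
    auto_granule_radius: tuple[float, float] = (2.0, 0.5)
    #: expected photons per organelle pixel at 1 uM, by class
    photons_per_organelle: dict[str, float] = Field(
        default_factory=lambda: {"LD": 100.0, "LRO": 400.0,
                                 "autofluorescence": 300.0})
    #: expected diffuse autofluorescence photons per worm-body pixel
    autofluorescence_level: float = 2.0
    #: concentration-law exponents by class (LD linear, LRO sub-linear)
    concentration_exponents: dict[str, float] = Field(
        default_factory=lambda: {"LD": 1.0, "LRO": 0.5,
                                 "autofluorescence": 0.0})
    #: minimum gap between organelle boundaries (px): organelles are
    #: resolvable structures, separated by at least one low-magnification
    #: (4x-pooled) pixel so they stay individually countable in the
    #: screening workflow, as they are in real intestinal images
    placement_margin_px: float = 5.0
    irf_sigma: float = 0.15
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "WormConfig":
        if min(self.n_LD, self.n_LRO, self.n_auto_granules) < 0:
            raise ValueError("organelle counts must be >= 0")
        for name in ("LD_radius", "LRO_radius", "auto_granule_radius"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have mean > 0 and sd >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.genotype is Genotype.GLO1 and self.n_LRO != 0:
            raise ValueError("glo1 worms lack LROs: n_LRO must be 0")
        if (self.genotype is Genotype.DAF22
                and self.LD_radius[0] < 2 * WT_LD_RADIUS_MEAN):
            raise ValueError(
                "daf22 worms have enlarged LDs: LD radius mean must be "
                f">= {2 * WT_LD_RADIUS_MEAN} px")
        return self


def preset_config(genotype: Genotype | str, *, seed: int = 0,
                  concentration: float = 1.0, **overrides) -> WormConfig:
    """Genotype presets encoding the phenotype anchors.

    glo1: no LROs.  daf22: 2x-enlarged LDs.  daf2_highfat: more LDs.
    hb101_lowfat: fewer LDs.  unstained_aged: no dye signal, bright
    autofluorescent granules and elevated diffuse autofluorescence.
    """
    genotype = Genotype(genotype)
    base: dict = {"genotype": genotype, "seed": seed,
                  "concentration": concentration}
    if genotype is Genotype.GLO1:
        base["n_LRO"] = 0
    elif genotype is Genotype.DAF22:
        base["LD_radius"] = (2 * WT_LD_RADIUS_MEAN, 1.0)
        base["n_LD"] = 8  # fewer, larger droplets
    elif genotype is Genotype.DAF2_HIGHFAT:
        base["n_LD"] = 20
    elif genotype is Genotype.HB101_LOWFAT:
        base["n_LD"] = 6
    elif genotype is Genotype.UNSTAINED_AGED:
        base.update(n_LD=0, n_LRO=0, n_auto_granules=12,
                    autofluorescence_level=6.0)
    base.update(overrides)
    return WormConfig(**base)


@dataclass
class LabelImage:
    """Integer organelle map (0 = background) with a label -> class table."""

    labels: np.ndarray
    class_of: dict[int, OrganelleClass]
    body_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_of)
        if missing:
            raise ValueError(f"labels without a class: {sorted(missing)}")

    def labels_of_class(self, cls: OrganelleClass | str) -> list[int]:
        cls = OrganelleClass(cls)
        return sorted(k for k, v in self.class_of.items() if v is cls)

    def mask_of(self, label: int) -> np.ndarray:
        if label not in self.class_of:
            raise KeyError(f"unknown label {label}")
        return self.labels == label


@dataclass
class FLIMStack:
    """Photon-count hypercube (time-bin, y, x) with bin edges and metadata."""

    counts: np.ndarray           # (T, Y, X) nonnegative integers
    bin_edges: np.ndarray        # (T + 1,) ns
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (T, Y, X)")
        if len(self.bin_edges) != self.counts.shape[0] + 1:
            raise ValueError("bin_edges length must be T + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    @property
    def total_image(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def concentration_scaling(cls: OrganelleClass | str, concentration: float,
                          exponents: dict[str, float] | None = None) -> float:
    """Photon-scale multiplier at the given dye concentration.

    Normalised to 1 at 1 uM.  Defaults: LD scale grows linearly with
    concentration while LRO scale grows like sqrt(concentration), so the
    unfiltered LD:LRO intensity ratio increases with concentration;
    autofluorescence is dye-independent.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    cls = OrganelleClass(cls)
    exps = {"LD": 1.0, "LRO": 0.5, "autofluorescence": 0.0}
    if exponents:
        exps.update(exponents)
    return float(concentration ** exps[cls.value])


def class_decay_model(cls: OrganelleClass | str,
                      irf_sigma: float = 0.15) -> DecayModel:
    """The decay model used to sample photons for each ground-truth class."""
    cls = OrganelleClass(cls)
    if cls is OrganelleClass.LRO:
        return lro_model(irf_sigma)
    if cls is OrganelleClass.LD:
        return ld_model(irf_sigma)
    return autofluorescence_model(irf_sigma)


# -- geometry ----------------------------------------------------------------

def _body_mask(shape: tuple[int, int]) -> np.ndarray:
    """Elliptical worm-body region filling most of the frame."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    ry, rx = 0.35 * shape[0], 0.45 * shape[1]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _disk_coords(cy: int, cx: int, r: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.nonzero((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r)


MAX_PLACEMENT_RETRIES = 1000


def _place_organelles(rng: np.random.Generator, config: WormConfig,
                      body: np.ndarray,
                      ) -> tuple[np.ndarray, dict[int, OrganelleClass]]:
    """Rejection-sample non-overlapping disks inside the body mask."""
    shape = config.image_shape
    labels = np.zeros(shape, dtype=np.uint16)
    occupied = ~body  # forbid organelles outside the body
    class_of: dict[int, OrganelleClass] = {}
    plan = ([(OrganelleClass.LD, config.LD_radius)] * config.n_LD
            + [(OrganelleClass.LRO, config.LRO_radius)] * config.n_LRO
            + [(OrganelleClass.AUTOFLUORESCENCE, config.auto_granule_radius)]
            * config.n_auto_granules)
    next_label = 1
    for cls, (r_mean, r_sd) in plan:
        radius = max(1.0, rng.normal(r_mean, r_sd))
        for _ in range(MAX_PLACEMENT_RETRIES):
            cy = rng.integers(0, shape[0])
            cx = rng.integers(0, shape[1])
            ys, xs = _disk_coords(cy, cx, radius, shape)
            if len(ys) == 0 or occupied[ys, xs].any():
                continue
            labels[ys, xs] = next_label
            my, mx = _disk_coords(cy, cx, radius + config.placement_margin_px,
                                  shape)
            occupied[my, mx] = True
            class_of[next_label] = cls
            next_label += 1
            break
        else:
            raise RuntimeError(
                f"could not place a {cls.value} organelle of radius "
                f"{radius:.1f} px after {MAX_PLACEMENT_RETRIES} retries "
                f"(genotype={config.genotype.value}, "
                f"shape={config.image_shape}, seed={config.seed})")
    return labels, class_of


# -- photon synthesis --------------------------------------------------------

def _deposit_photons(stack: np.ndarray, rng: np.random.Generator,
                     model: DecayModel, expected: np.ndarray,
                     bin_edges: np.ndarray) -> None:
    """Sample Poisson photon counts per pixel and bin their arrival times."""
    ys, xs = np.nonzero(expected > 0)
    if len(ys) == 0:
        return
    n_per_px = rng.poisson(expected[ys, xs])
    total = int(n_per_px.sum())
    if total == 0:
        return
    times = sample_arrival_times(model, total, rng)
    t_idx = np.clip(np.searchsorted(bin_edges, times, side="right") - 1,
                    0, len(bin_edges) - 2)
    px = np.repeat(np.arange(len(ys)), n_per_px)
    np.add.at(stack, (t_idx, ys[px], xs[px]), 1)


def generate_worm(config: WormConfig) -> tuple[FLIMStack, LabelImage]:
    """Generate one synthetic worm: FLIM stack plus ground-truth labels.

    Per-pixel photon histograms are Poisson draws from the class decay
    models; organelle brightness is the class base rate times the
    concentration multiplier times a per-organelle log-normal factor
    (sigma_log = 0.3).  Diffuse autofluorescence covers the whole body.
    """
    rng = np.random.default_rng(config.seed)
    bin_edges = default_bin_edges()
    body = _body_mask(config.image_shape)
    labels, class_of = _place_organelles(rng, config, body)

    shape = config.image_shape
    stack = np.zeros((len(bin_edges) - 1, *shape), dtype=np.uint16)

    # per-class expected-count maps
    expected = {cls: np.zeros(shape) for cls in OrganelleClass}
    for label, cls in class_of.items():
        base = config.photons_per_organelle[cls.value]
        scale = concentration_scaling(cls, config.concentration,
                                      config.concentration_exponents)
        brightness = float(rng.lognormal(mean=0.0, sigma=0.3))
        expected[cls][labels == label] = base * scale * brightness
    if config.autofluorescence_level > 0:
        expected[OrganelleClass.AUTOFLUORESCENCE][body] += \
            config.autofluorescence_level

    for cls in OrganelleClass:  # fixed order: LD, LRO, autofluorescence
        _deposit_photons(stack, rng, class_decay_model(cls, config.irf_sigma),
                         expected[cls], bin_edges)

    meta = {"config": config.model_dump(mode="json"), "seed": config.seed}
    return (FLIMStack(stack, bin_edges, meta),
            LabelImage(labels, class_of, body_mask=body))


def generate_population(configs: Iterable[WormConfig],
                        ) -> list[tuple[FLIMStack, LabelImage]]:
    """Independent seeded worms; warns if two configs share a seed."""
    configs = list(configs)
    if not configs:
        raise ValueError("generate_population needs at least one WormConfig")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) < len(seeds):
        logger.warning("duplicate seeds across worms in population: %s", seeds)
    return [generate_worm(c) for c in configs]


ScreenPreset = Literal["screen_daf22", "screen_glo1", "screen_wt"]

#: Screening is done at 8 uM BODIPY, the concentration with the best
#: LD:LRO contrast under FLF.
SCREEN_CONCENTRATION_UM = 8.0


def screen_configs(preset: ScreenPreset, base_seed: int = 0,
                   n_worms: int = 10) -> list[WormConfig]:
    """Population presets for the simulated forward-genetic screen.

    ``screen_daf22`` / ``screen_glo1``: nine wild-type worms and one mutant,
    the mutant's position drawn from ``base_seed``.  ``screen_wt``: all
    wild-type (specificity control).
    """
    rng = np.random.default_rng(base_seed)
    mutant_idx = int(rng.integers(n_worms))
    mutant = {"screen_daf22": Genotype.DAF22, "screen_glo1": Genotype.GLO1,
              "screen_wt": None}[preset]
    configs = []
    for i in range(n_worms):
        geno = mutant if (mutant is not None and i == mutant_idx) \
            else Genotype.WT
        configs.append(preset_config(geno, seed=base_seed * n_worms + i + 1,
                                     concentration=SCREEN_CONCENTRATION_UM))
    return configs
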
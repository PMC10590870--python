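"""Study-condition defaults and configuration containers.

The default parameter tables encode the published group statistics of a 7 T
MRSI cohort of relapsing-remitting MS patients: per-group metabolite-ratio
means/SDs for the four iron-accumulation lesion types and NAWM, the
periphery-normalized concentric-layer profiles of non-iron vs iron lesions,
and the three-epoch ratio means of newly emerging lesions. The synthetic
cohort generator treats these as ground-truth population parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

#: the four metabolite ratios carried through every analysis stage
RATIOS: tuple[str, ...] = ("mIns/tNAA", "mIns/tCr", "tNAA/tCr", "tCho/tCr")

LAYER_NAMES: tuple[str, ...] = ("L+3", "L+2", "L+1", "L0", "L-1", "L-2", "L-3")
EPOCHS: tuple[str, ...] = ("year_minus1", "year0", "year1")


class IronType(str, Enum):
    """Iron-accumulation category of a lesion on susceptibility imaging."""

    NON_IRON = "non_iron"
    AREA = "area"          # diffuse iron accumulation covering the whole lesion
    TRANSITION = "transition"  # intermediate between area and rim
    RIM = "rim"            # distinct paramagnetic rim

    @property
    def is_iron(self) -> bool:
        return self is not IronType.NON_IRON


def iron_group(iron_type: IronType | str) -> str:
    """Collapse the four types into the binary iron / non-iron grouping."""
    t = IronType(iron_type)
    return "iron" if t.is_iron else "non_iron"


# ---------------------------------------------------------------------------
# Published cohort statistics (population parameters of the generator)
# ---------------------------------------------------------------------------

#: segmented lesion counts per type (full cohort, before the size filter)
SEGMENTED_LESION_COUNTS: dict[str, int] = {
    "non_iron": 412, "area": 31, "transition": 8, "rim": 36,
}
#: lesion counts per type that met the >20 mm^3 size criterion
INCLUDED_LESION_COUNTS: dict[str, int] = {
    "non_iron": 174, "area": 13, "transition": 7, "rim": 26,
}

NAWM_RATIO_MEANS: dict[str, float] = {
    "mIns/tNAA": 0.53, "mIns/tCr": 0.85, "tNAA/tCr": 1.67, "tCho/tCr": 0.46,
}
NAWM_RATIO_SDS: dict[str, float] = {
    "mIns/tNAA": 0.17, "mIns/tCr": 0.30, "tNAA/tCr": 0.37, "tCho/tCr": 0.08,
}

LESION_RATIO_MEANS: dict[str, dict[str, float]] = {
    "non_iron":  {"mIns/tNAA": 1.13, "mIns/tCr": 1.08, "tNAA/tCr": 1.08, "tCho/tCr": 0.42},
    "area":      {"mIns/tNAA": 0.93, "mIns/tCr": 1.19, "tNAA/tCr": 1.37, "tCho/tCr": 0.43},
    "transition":{"mIns/tNAA": 1.04, "mIns/tCr": 1.14, "tNAA/tCr": 1.16, "tCho/tCr": 0.45},
    "rim":       {"mIns/tNAA": 1.53, "mIns/tCr": 1.19, "tNAA/tCr": 1.00, "tCho/tCr": 0.40},
}
LESION_RATIO_SDS: dict[str, dict[str, float]] = {
    "non_iron":  {"mIns/tNAA": 0.58, "mIns/tCr": 0.36, "tNAA/tCr": 0.39, "tCho/tCr": 0.07},
    "area":      {"mIns/tNAA": 0.30, "mIns/tCr": 0.49, "tNAA/tCr": 0.62, "tCho/tCr": 0.08},
    "transition":{"mIns/tNAA": 0.42, "mIns/tCr": 0.38, "tNAA/tCr": 0.52, "tCho/tCr": 0.05},
    "rim":       {"mIns/tNAA": 0.97, "mIns/tCr": 0.37, "tNAA/tCr": 0.47, "tCho/tCr": 0.10},
}

#: periphery-normalized layer anchors (L+3 == 1 by construction); only the
#: innermost (L-3) and outermost in-lesion (L0) layers are reported, split by
#: the binary iron grouping
LAYER_ANCHOR_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "non_iron": {
        "mIns/tNAA": {"L0": 1.11, "L-3": 1.15},
        "mIns/tCr":  {"L0": 1.01, "L-3": 1.00},
        "tNAA/tCr":  {"L0": 0.89, "L-3": 0.85},
        "tCho/tCr":  {"L0": 0.99, "L-3": 0.98},
    },
    "iron": {
        "mIns/tNAA": {"L0": 1.23, "L-3": 1.40},
        "mIns/tCr":  {"L0": 1.05, "L-3": 1.03},
        "tNAA/tCr":  {"L0": 0.83, "L-3": 0.65},
        "tCho/tCr":  {"L0": 0.96, "L-3": 0.91},
    },
}
LAYER_ANCHOR_SDS: dict[str, dict[str, dict[str, float]]] = {
    "non_iron": {
        "mIns/tNAA": {"L0": 0.11, "L-3": 0.26},
        "mIns/tCr":  {"L0": 0.07, "L-3": 0.15},
        "tNAA/tCr":  {"L0": 0.11, "L-3": 0.29},
        "tCho/tCr":  {"L0": 0.07, "L-3": 0.11},
    },
    "iron": {
        "mIns/tNAA": {"L0": 0.11, "L-3": 0.34},
        "mIns/tCr":  {"L0": 0.07, "L-3": 0.10},
        "tNAA/tCr":  {"L0": 0.08, "L-3": 0.16},
        "tCho/tCr":  {"L0": 0.05, "L-3": 0.08},
    },
}

#: newly-emerging-lesion ratio means per epoch (Year -1, Year 0, Year 1),
#: split by binary iron status; "all_new" is the published pooled group
LONGITUDINAL_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    "all_new": {
        "mIns/tNAA": (0.74, 1.17, 1.26), "mIns/tCr": (0.84, 0.94, 1.03),
        "tNAA/tCr": (1.30, 0.90, 0.97), "tCho/tCr": (0.52, 0.53, 0.47),
    },
    "iron": {
        "mIns/tNAA": (0.73, 1.41, 1.33), "mIns/tCr": (0.82, 1.11, 1.06),
        "tNAA/tCr": (1.22, 0.84, 0.92), "tCho/tCr": (0.50, 0.52, 0.46),
    },
    "non_iron": {
        "mIns/tNAA": (0.75, 0.85, 1.05), "mIns/tCr": (0.86, 0.79, 0.95),
        "tNAA/tCr": (1.42, 0.94, 1.08), "tCho/tCr": (0.54, 0.53, 0.50),
    },
}
LONGITUDINAL_SDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "all_new": {
        "mIns/tNAA": (0.31, 0.41, 0.76), "mIns/tCr": (0.35, 0.32, 0.19),
        "tNAA/tCr": (0.34, 0.19, 0.31), "tCho/tCr": (0.09, 0.09, 0.05),
    },
    "iron": {
        "mIns/tNAA": (0.22, 0.35, 0.82), "mIns/tCr": (0.32, 0.35, 0.16),
        "tNAA/tCr": (0.29, 0.19, 0.27), "tCho/tCr": (0.05, 0.09, 0.05),
    },
    "non_iron": {
        "mIns/tNAA": (0.44, 0.24, 0.59), "mIns/tCr": (0.40, 0.20, 0.25),
        "tNAA/tCr": (0.38, 0.20, 0.41), "tCho/tCr": (0.13, 0.09, 0.06),
    },
}

#: counts of newly emerging lesions with spectroscopic data
NEW_LESION_COUNTS: dict[str, int] = {"non_iron": 11, "iron": 16}


def default_iron_type_probs() -> dict[str, float]:
    total = sum(SEGMENTED_LESION_COUNTS.values())
    return {k: v / total for k, v in SEGMENTED_LESION_COUNTS.items()}


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class SpectrumConfig:
    """Spectral axis, fit window and noise level of the MRSI forward model.

    ppm axis is stored ascending; ppm <-> Hz conversion uses the proton
    transmitter frequency (297.2 MHz at 7 T). ``noise_sd`` is the SD of the
    additive Gaussian noise per real/imaginary channel, in units where the
    total-creatine amplitude of a nominal NAWM voxel is 1.
    """

    n_points: int = 512
    ppm_range: tuple[float, float] = (0.2, 5.0)
    transmitter_freq_mhz: float = 297.2
    fit_range_ppm: tuple[float, float] = (1.8, 4.2)
    noise_sd: float = 0.12
    noise_window_ppm: tuple[float, float] | None = None  # default: upper 10%

    def __post_init__(self) -> None:
        if self.n_points < 256:
            raise ValueError("n_points must be >= 256")
        lo, hi = self.ppm_range
        flo, fhi = self.fit_range_ppm
        if not (lo < hi and lo <= flo < fhi <= hi):
            raise ValueError("fit_range_ppm must lie within ppm_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)

    @property
    def hz_per_ppm(self) -> float:
        return self.transmitter_freq_mhz

    def noise_window(self) -> tuple[float, float]:
        if self.noise_window_ppm is not None:
            return self.noise_window_ppm
        lo, hi = self.ppm_range
        return (hi - 0.10 * (hi - lo), hi)


def _zeroed(d):
    if isinstance(d, dict):
        return {k: _zeroed(v) for k, v in d.items()}
    if isinstance(d, (tuple, list)):
        return type(d)(_zeroed(v) for v in d)
    return 0.0


@dataclass
class PhantomConfig:
    """Every knob of the synthetic cohort generator.

    The defaults are the study conditions of the emulated cohort: group
    prevalences of the four iron types, per-(type, ratio) means/SDs, layer
    anchors and longitudinal epoch means. Geometry is deliberately schematic
    (spherical lesions inside concentric WM/GM/CSF compartments) because
    every downstream operator consumes only masks and voxel values.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)

    # lesion population
    n_lesions: int = 16
    lesion_radius_range_mm: tuple[float, float] = (2.8, 4.5)
    iron_type_probs: dict[str, float] = field(default_factory=default_iron_type_probs)

    # ratio-map values
    nawm_ratio_means: dict[str, float] = field(default_factory=lambda: dict(NAWM_RATIO_MEANS))
    nawm_ratio_sds: dict[str, float] = field(default_factory=lambda: dict(NAWM_RATIO_SDS))
    lesion_ratio_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in LESION_RATIO_MEANS.items()})
    lesion_ratio_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in LESION_RATIO_SDS.items()})
    layer_profile_means: dict = field(
        default_factory=lambda: {g: {r: dict(v) for r, v in d.items()}
                                 for g, d in LAYER_ANCHOR_MEANS.items()})
    layer_profile_sds: dict = field(
        default_factory=lambda: {g: {r: dict(v) for r, v in d.items()}
                                 for g, d in LAYER_ANCHOR_SDS.items()})
    noise_sd_map: dict[str, float] = field(default_factory=lambda: {
        "mIns/tNAA": 0.15, "mIns/tCr": 0.12, "tNAA/tCr": 0.15, "tCho/tCr": 0.05})
    #: correlation length of the smooth NAWM variability field; the field's
    #: amplitude is nawm_ratio_sds, emulating regional NAWM heterogeneity
    nawm_field_correlation_mm: float = 4.0
    #: "group_mean": volume-weighted lesion mean equals the configured group
    #: mean (ROI statistics cohorts). "periphery": lesion values continuous
    #: with the local NAWM level so that periphery-normalized layer profiles
    #: reproduce the configured anchors (layer-analysis cohorts).
    lesion_scaling: str = "group_mean"

    # susceptibility volume
    swi_background: float = 100.0
    swi_noise_sd: float = 2.0
    swi_delta: float = 40.0
    #: relative depth (fraction of lesion radius) where the graded
    #: transition-type hypointensity fades to zero
    transition_fade_depth: float = 0.45

    # anatomy (concentric compartments)
    brain_radius_frac: float = 0.45
    gm_thickness_mm: float = 3.2
    csf_thickness_mm: float = 2.4

    # longitudinal cohort
    n_new_lesions: int = 27
    new_lesion_iron_prob: float = 16.0 / 27.0
    longitudinal_means: dict = field(
        default_factory=lambda: {g: dict(d) for g, d in LONGITUDINAL_MEANS.items()})
    longitudinal_sds: dict = field(
        default_factory=lambda: {g: dict(d) for g, d in LONGITUDINAL_SDS.items()})

    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        psum = sum(self.iron_type_probs.values())
        if abs(psum - 1.0) > 1e-12:
            raise ValueError(f"iron_type_probs must sum to 1, got {psum!r}")
        if any(p < 0 for p in self.iron_type_probs.values()):
            raise ValueError("iron_type_probs must be non-negative")
        rmin, rmax = self.lesion_radius_range_mm
        if not (0 < rmin <= rmax):
            raise ValueError("lesion radius range must be positive with min <= max")
        for d in (self.nawm_ratio_sds, self.noise_sd_map):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")
        for tdict in self.lesion_ratio_sds.values():
            if any(v < 0 for v in tdict.values()):
                raise ValueError("standard deviations must be >= 0")
        if self.lesion_scaling not in ("group_mean", "periphery"):
            raise ValueError("lesion_scaling must be 'group_mean' or 'periphery'")
        if self.n_lesions < 0 or self.n_new_lesions < 0:
            raise ValueError("lesion counts must be >= 0")

    # -- convenience --------------------------------------------------------

    def noise_free(self) -> "PhantomConfig":
        """A copy with every stochastic amplitude zeroed (calibration checks)."""
        return dataclasses.replace(
            self,
            nawm_ratio_sds=_zeroed(self.nawm_ratio_sds),
            lesion_ratio_sds=_zeroed(self.lesion_ratio_sds),
            layer_profile_sds=_zeroed(self.layer_profile_sds),
            noise_sd_map=_zeroed(self.noise_sd_map),
            longitudinal_sds=_zeroed(self.longitudinal_sds),
            swi_noise_sd=0.0,
            spectrum=dataclasses.replace(self.spectrum, noise_sd=0.0),
        )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))  # tuples -> lists

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "spectrum" in d and isinstance(d["spectrum"], dict):
            d["spectrum"] = SpectrumConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["spectrum"].items()})
        for key in ("grid_shape", "voxel_size_mm", "lesion_radius_range_mm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, default=list))
        else:
            path.write_text(yaml.safe_dump(d, default_flow_style=None))
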
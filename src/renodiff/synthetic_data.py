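"""Digital renal DWI phantoms: tissue presets, acquisition schemes,
labeled geometry, multi-exponential signal generation and Rician noise.

Tissue presets carry published per-tissue reference values (mean and SD)
for MD, FA [-], f_star, f_fast, f_interm [%] and D_bi, D_tri
[1e-3 mm^2/s]; they drive both noise-free ground-truth phantoms and
cohort-level random draws for statistics testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from renodiff.exceptions import ValidationError
from renodiff.fitting import DEFAULT_BOUNDS
from renodiff.io_formats import AcquisitionScheme, LabeledVolume
from renodiff.signal_models import (
    D_FAST_DEFAULT,
    D_INTERM_DEFAULT,
    D_STAR_DEFAULT,
    BiExpParams,
    TensorFit,
    TriExpParams,
    predict_tensor,
    predict_triexp,
    tensor_from_md_fa,
)

log = logging.getLogger(__name__)

IVIM_BVALUES = (0.0, 10.0, 25.0, 40.0, 75.0, 100.0, 200.0, 300.0, 500.0, 700.0)
DTI_BVALUES = (0.0, 100.0, 300.0)

#: classic balanced 6-direction set (pairs of axes at 45 degrees)
_SQ = 1.0 / np.sqrt(2.0)
DIRECTIONS_6 = np.array(
    [
        [_SQ, _SQ, 0.0],
        [_SQ, 0.0, _SQ],
        [0.0, _SQ, _SQ],
        [_SQ, -_SQ, 0.0],
        [_SQ, 0.0, -_SQ],
        [0.0, _SQ, -_SQ],
    ]
)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n approximately uniformly spread unit vectors on the upper hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = i / n  # (0, 1): strictly upper hemisphere, pairwise non-collinear
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def protocol_scheme(kind: str) -> AcquisitionScheme:
    """Acquisition scheme of the emulated protocol.

    ``ivim``: one b=0 volume plus nine nonzero b-values (10, 25, 40, 75,
    100, 200, 300, 500, 700 s/mm^2), each along six directions.
    ``dti``: one b=0 volume plus b = 100 and 300 s/mm^2 along fifteen
    spread directions (31 volumes).
    """
    if kind == "ivim":
        bvals = [0.0]
        dirs = [np.zeros(3)]
        for b in IVIM_BVALUES[1:]:
            for g in DIRECTIONS_6:
                bvals.append(b)
                dirs.append(g)
    elif kind == "dti":
        dirs15 = fibonacci_hemisphere(15)
        bvals = [0.0]
        dirs = [np.zeros(3)]
        for b in DTI_BVALUES[1:]:
            for g in dirs15:
                bvals.append(b)
                dirs.append(g)
    else:
        raise ValidationError(f"unknown scheme kind {kind!r}; choose 'ivim' or 'dti'")
    return AcquisitionScheme(np.array(bvals), np.array(dirs))


# ---------------------------------------------------------------------------
# tissue presets


@dataclass(frozen=True)
class TissuePreset:
    """Reference diffusion parameters of one tissue / lesion type.

    Fractions are stored in percent and diffusivities in 1e-3 mm^2/s
    (table convention); the ``*_params`` accessors convert to model
    units.  SDs are zero for single-case presets.
    """

    name: str
    md: float
    fa: float
    f_star: float  # percent
    d_bi: float
    f_fast: float  # percent
    f_interm: float  # percent
    d_tri: float
    md_sd: float = 0.0
    fa_sd: float = 0.0
    f_star_sd: float = 0.0
    d_bi_sd: float = 0.0
    f_fast_sd: float = 0.0
    f_interm_sd: float = 0.0
    d_tri_sd: float = 0.0
    group: str = "lesion"

    def triexp_params(
        self,
        s0: float = 1.0,
        d_fast: float = D_FAST_DEFAULT,
        d_interm: float = D_INTERM_DEFAULT,
    ) -> TriExpParams:
        return TriExpParams(
            S0=s0,
            f_fast=self.f_fast / 100.0,
            D_fast=d_fast,
            f_interm=self.f_interm / 100.0,
            D_interm=d_interm,
            D_tri=self.d_tri,
        )

    def biexp_params(self, s0: float = 1.0, d_star: float = D_STAR_DEFAULT) -> BiExpParams:
        return BiExpParams(S0=s0, f_star=self.f_star / 100.0, D_star=d_star, D_bi=self.d_bi)

    def tensor_params(self, s0: float = 1.0, axis=(0.0, 0.0, 1.0)) -> TensorFit:
        return tensor_from_md_fa(self.md, self.fa, axis=axis, S0=s0)

    @property
    def means(self) -> dict:
        return {
            "MD": self.md, "FA": self.fa, "f_star": self.f_star, "D_bi": self.d_bi,
            "f_fast": self.f_fast, "f_interm": self.f_interm, "D_tri": self.d_tri,
        }

    @property
    def sds(self) -> dict:
        return {
            "MD": self.md_sd, "FA": self.fa_sd, "f_star": self.f_star_sd,
            "D_bi": self.d_bi_sd, "f_fast": self.f_fast_sd,
            "f_interm": self.f_interm_sd, "D_tri": self.d_tri_sd,
        }


def _p(name, md, fa, fs, dbi, ff, fi, dt, sds=(0,) * 7, group="lesion"):
    return TissuePreset(
        name, md, fa, fs, dbi, ff, fi, dt,
        md_sd=sds[0], fa_sd=sds[1], f_star_sd=sds[2], d_bi_sd=sds[3],
        f_fast_sd=sds[4], f_interm_sd=sds[5], d_tri_sd=sds[6], group=group,
    )


#: named reference parameter sets (grouped tissues first, then individual
#: lesion variants); columns: MD, FA, f_star%, D_bi, f_fast%, f_interm%, D_tri
PRESETS = {
    p.name: p
    for p in [
        _p("healthy_cortex", 2.16, 0.38, 10.1, 1.93, 4.14, 28.8, 1.41,
           (0.12, 0.09, 2.58, 0.10, 1.92, 5.09, 0.09), group="cortex"),
        _p("healthy_medulla", 2.21, 0.39, 9.69, 2.02, 4.57, 26.4, 1.55,
           (0.14, 0.08, 2.90, 0.11, 1.74, 6.65, 0.12), group="medulla"),
        _p("all_solid_lesions", 1.94, 0.47, 11.6, 1.71, 7.30, 18.7, 1.39,
           (0.32, 0.11, 3.88, 0.43, 3.29, 5.02, 0.35), group="solid"),
        _p("rcc", 1.90, 0.46, 11.6, 1.65, 7.21, 18.3, 1.34,
           (0.32, 0.10, 3.45, 0.40, 2.88, 5.35, 0.33), group="rcc"),
        _p("cyst", 3.04, 0.37, 1.88, 2.90, 1.18, 8.31, 2.74,
           (0.17, 0.11, 1.60, 0.11, 1.70, 2.02, 0.08), group="cyst"),
        _p("benign", 2.18, 0.48, 11.6, 2.04, 7.76, 20.9, 1.68,
           (0.28, 0.19, 7.83, 0.58, 6.75, 2.43, 0.45), group="benign"),
        _p("cc_rcc", 1.94, 0.46, 11.6, 1.71, 7.36, 18.8, 1.38,
           (0.33, 0.12, 3.62, 0.42, 3.14, 5.78, 0.34), group="rcc"),
        _p("cc_rcc_sarcomatoid_necrotic_hemorrhagic", 1.77, 0.58, 12.5, 1.38, 7.83, 20.1, 1.04, group="rcc"),
        _p("cc_rcc_extensive_necrosis", 1.19, 0.64, 10.78, 0.92, 6.13, 15.11, 0.71, group="rcc"),
        _p("cc_rcc_papillary_growth", 1.82, 0.28, 16.5, 1.49, 11.2, 20.6, 1.19, group="rcc"),
        _p("cc_rcc_nested_erythrocyte_extravasation", 1.94, 0.40, 14.29, 1.71, 9.11, 22.25, 1.71, group="rcc"),
        _p("cc_rcc_low_density_hemorrhagic_cystic", 2.24, 0.57, 10.35, 1.90, 6.22, 12.46, 1.68, group="rcc"),
        _p("cc_rcc_extensive_hemorrhage", 2.01, 0.46, 16.62, 1.71, 12.43, 16.09, 1.49, group="rcc"),
        _p("cc_rcc_cystic_solid", 2.20, 0.45, 8.69, 1.97, 6.25, 15.31, 1.69, group="rcc"),
        _p("cc_rcc_microcystic_hemorrhagic", 2.17, 0.36, 7.95, 2.39, 2.83, 31.72, 1.68, group="rcc"),
        _p("p_rcc", 1.68, 0.50, 11.3, 1.36, 6.56, 16.3, 1.14,
           (0.20, 0.01, 3.8, 0.06, 1.80, 2.88, 0.06), group="rcc"),
        _p("hemangioma", 2.38, 0.61, 6.06, 2.45, 2.99, 22.6, 1.99, group="benign"),
        _p("oncocytoma", 1.98, 0.34, 17.1, 1.63, 12.5, 19.2, 1.36, group="benign"),
    ]
}

#: bounds used to truncate cohort draws, keyed by table column
_DRAW_BOUNDS = {
    "MD": (0.01, 4.0),
    "FA": (0.0, 0.99),
    "f_star": (0.0, 100.0),
    "D_bi": DEFAULT_BOUNDS["D_bi"],
    "f_fast": (0.0, 100.0),
    "f_interm": (0.0, 100.0),
    "D_tri": DEFAULT_BOUNDS["D_tri"],
}


# ---------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + ground truth + noise level of a digital phantom.

    ``regions`` maps label id -> (tissue name, geometry), where geometry
    is ``("ellipsoid", center, radii)`` or ``("box", lower, upper)`` in
    voxel coordinates.  ``params`` maps label id -> TissuePreset.
    Regions must not overlap.
    """

    shape: tuple = (32, 32, 8)
    voxel_size: tuple = (3.0, 3.0, 3.0)
    regions: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    s0: float = 100.0
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValidationError("SNR must be > 0")
        missing = set(self.regions) - set(self.params)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} lack parameters")

    @property
    def sigma(self) -> float:
        return self.s0 / self.snr


def _region_mask(shape, geometry) -> np.ndarray:
    kind = geometry[0]
    grid = np.indices(shape).astype(float)
    if kind == "ellipsoid":
        _, center, radii = geometry
        r = sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3))
        return r <= 1.0
    if kind == "box":
        _, lower, upper = geometry
        m = np.ones(shape, dtype=bool)
        for i in range(3):
            m &= (grid[i] >= lower[i]) & (grid[i] < upper[i])
        return m
    raise ValidationError(f"unknown geometry kind {kind!r}")


def build_labels(spec: PhantomSpec) -> LabeledVolume:
    """Rasterize the region geometry into a label map (overlap is an error)."""
    data = np.zeros(spec.shape, dtype=np.int32)
    names = {}
    for label, (name, geometry) in sorted(spec.regions.items()):
        m = _region_mask(spec.shape, geometry)
        if np.any(data[m] != 0):
            raise ValidationError(f"region {label} ({name}) overlaps an earlier region")
        data[m] = label
        names[label] = name
    return LabeledVolume(data, spec.voxel_size, names)


def default_phantom_spec(
    presets=("healthy_cortex", "healthy_medulla", "cyst"),
    shape=(32, 32, 8),
    snr: float = 50.0,
    seed: int = 0,
    s0: float = 100.0,
) -> PhantomSpec:
    """Phantom with one box region per preset, side by side along x."""
    n = len(presets)
    nx = shape[0] // n
    regions, params = {}, {}
    for i, name in enumerate(presets):
        if name not in PRESETS:
            raise ValidationError(f"unknown tissue preset {name!r}")
        lo = (i * nx + 1, 1, 1)
        hi = ((i + 1) * nx - 1, shape[1] - 1, shape[2] - 1)
        regions[i + 1] = (name, ("box", lo, hi))
        params[i + 1] = PRESETS[name]
    return PhantomSpec(shape=shape, regions=regions, params=params, s0=s0, snr=snr, seed=seed)


def make_phantom(spec: PhantomSpec, scheme: AcquisitionScheme, model: str = "triexp"):
    """Noise-free 4D phantom from per-label forward models.

    ``model`` selects the generator: ``triexp`` evaluates each label's
    three-compartment decay (direction-independent), ``tensor`` evaluates
    the axially symmetric tensor built from the label's MD/FA.  Returns
    ``(volume4d, LabeledVolume, truth_maps)`` where truth_maps holds one
    3D ground-truth map per parameter (NaN outside labels).
    """
    labels = build_labels(spec)
    volume = np.zeros(spec.shape + (len(scheme),))
    if model == "triexp":
        truth_names = ("S0", "f_fast", "D_fast", "f_interm", "D_interm", "D_tri", "f_slow")
    elif model == "tensor":
        truth_names = ("S0", "MD", "FA")
    else:
        raise ValidationError(f"unknown phantom model {model!r}")
    truth = {name: np.full(spec.shape, np.nan) for name in truth_names}

    for label, preset in spec.params.items():
        m = labels.mask(label)
        if not m.any():
            continue
        if model == "triexp":
            p = preset.triexp_params(s0=spec.s0)
            sig = predict_triexp(p, scheme.bvalues)
            values = {
                "S0": p.S0, "f_fast": p.f_fast, "D_fast": p.D_fast,
                "f_interm": p.f_interm, "D_interm": p.D_interm,
                "D_tri": p.D_tri, "f_slow": p.f_slow,
            }
        else:
            t = preset.tensor_params(s0=spec.s0)
            sig = predict_tensor(t, scheme.bvalues, scheme.directions)
            values = {"S0": t.S0, "MD": preset.md, "FA": preset.fa}
        volume[m] = sig
        for name, v in values.items():
            truth[name][m] = v
    return volume, labels, truth


def add_rician_noise(volume, sigma: float, seed=None) -> np.ndarray:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n_i ~ N(0, sigma).

    ``seed`` may be an int or a numpy Generator; sigma = 0 returns the
    input unchanged.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if sigma == 0:
        return volume.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# cohort sampling


def draw_tissue_values(preset: TissuePreset, rng: np.random.Generator) -> dict:
    """One random tissue realization: Gaussian draws around the preset
    means with the preset SDs, truncated to physical bounds by repeated
    resampling."""
    out = {}
    for key, mean in preset.means.items():
        sd = preset.sds[key]
        lo, hi = _DRAW_BOUNDS[key]
        if sd == 0:
            out[key] = float(np.clip(mean, lo, hi))
            continue
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                break
        out[key] = float(np.clip(v, lo, hi))
    # keep the fraction sum valid for the tri-exponential generator
    total = out["f_fast"] + out["f_interm"]
    if total > 99.0:
        out["f_fast"] *= 99.0 / total
        out["f_interm"] *= 99.0 / total
    return out


DEFAULT_SOLID_MIX = (
    ("cc_rcc",) * 9 + ("p_rcc",) * 2 + ("hemangioma", "oncocytoma")
)


def sample_cohort(
    n_solid: int = 13,
    n_cysts: int = 5,
    solid_mix=DEFAULT_SOLID_MIX,
    snr: Optional[float] = None,
    seed: int = 0,
    make_images: bool = False,
    lesion_shape=(10, 10, 6),
):
    """Synthetic patient cohort mirroring a paired healthy/lesion design.

    Each of ``max(n_solid, n_cysts)`` patients gets a healthy-cortex and a
    healthy-medulla draw; patient i < n_solid additionally hosts the i-th
    solid lesion of ``solid_mix`` and patient i < n_cysts a cyst.  Returns
    ``(datasets, truth)``: a list of per-lesion dataset dicts (only
    populated when ``make_images`` is set) and a tidy table with one row
    per tissue observation (columns: patient, lesion_id, tissue, group
    and the seven diffusion parameters, fractions in percent).
    """
    if n_solid < 1:
        raise ValidationError("need at least one solid lesion")
    if len(solid_mix) < n_solid:
        raise ValidationError("solid_mix is shorter than n_solid")
    rng = np.random.default_rng(seed)
    n_patients = max(n_solid, n_cysts)
    rows, datasets = [], []

    def add_row(patient, lesion_id, tissue, group, values):
        rows.append({"patient": patient, "lesion_id": lesion_id,
                     "tissue": tissue, "group": group, **values})
        return values

    lesion_counter = 0
    for patient in range(1, n_patients + 1):
        add_row(patient, None, "healthy_cortex", "cortex",
                draw_tissue_values(PRESETS["healthy_cortex"], rng))
        add_row(patient, None, "healthy_medulla", "medulla",
                draw_tissue_values(PRESETS["healthy_medulla"], rng))
        lesions_here = []
        if patient <= n_solid:
            lesions_here.append(solid_mix[patient - 1])
        if patient <= n_cysts:
            lesions_here.append("cyst")
        for tissue in lesions_here:
            lesion_counter += 1
            preset = PRESETS[tissue]
            values = add_row(patient, lesion_counter, tissue, preset.group,
                             draw_tissue_values(preset, rng))
            entry = {"lesion_id": lesion_counter, "tissue": tissue,
                     "group": preset.group, "truth": values}
            if make_images:
                drawn = TissuePreset(
                    name=tissue, md=values["MD"], fa=values["FA"],
                    f_star=values["f_star"], d_bi=values["D_bi"],
                    f_fast=values["f_fast"], f_interm=values["f_interm"],
                    d_tri=values["D_tri"], group=preset.group,
                )
                shape = lesion_shape
                spec = PhantomSpec(
                    shape=shape,
                    regions={1: (tissue, ("ellipsoid",
                                          tuple((s - 1) / 2.0 for s in shape),
                                          tuple(s / 2.0 - 1.0 for s in shape)))},
                    params={1: drawn},
                    snr=snr or 50.0,
                    seed=seed + lesion_counter,
                )
                scheme = protocol_scheme("ivim")
                vol, labels, truth_maps = make_phantom(spec, scheme)
                if snr:
                    vol = add_rician_noise(vol, spec.sigma, rng)
                entry.update(volume=vol, scheme=scheme, labels=labels,
                             truth_maps=truth_maps)
            datasets.append(entry)
    truth = pd.DataFrame(rows)
    return datasets, truth
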
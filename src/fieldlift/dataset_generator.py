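"""Paired low-field / high-field corpus generation with data augmentation.

One *paired sample* is a single metabolite mixture rendered at both 100 MHz
and 400 MHz on the same ppm grid.  Everything that describes the underlying
sample — composition, per-metabolite chemical-shift jitter, artifact peaks,
baseline offset — is drawn once and shared between the two renderings; only
the thermal noise is drawn independently per field (optionally with a larger
amplitude at low field to emulate the poorer SNR of benchtop magnets).

Augmentation amplitudes are expressed as fractions of the quantitative
reference peak height.  The reference is a 9-proton singlet at 0.0 ppm
(TSP-d4 style) at a fixed concentration, and the normalizing "height" is its
analytic peak height (concentration x proton count under the unit-height
amplitude convention), which keeps noise and baseline scales independent of
grid resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

from . import __version__
from .spectral_core import (
    DEFAULT_N_POINTS,
    DEFAULT_PPM_MAX,
    DEFAULT_PPM_MIN,
    HF_FREQ_MHZ,
    LF_FREQ_MHZ,
    MetaboliteSpinModel,
    Multiplet,
    SpectralAxis,
    SpectrumRecord,
    ValidationError,
    library_hash,
    make_axis,
    render_metabolite,
    render_multiplet,
)

__all__ = [
    "REFERENCE_NAME",
    "REFERENCE_PROTONS",
    "ARTIFACT_TRIPLET_J_HZ",
    "AugmentationConfig",
    "CorpusConfig",
    "PairedSample",
    "draw_composition",
    "add_reference",
    "add_noise",
    "jitter_metabolite",
    "shift_baseline",
    "draw_artifacts",
    "add_artifacts",
    "generate_paired_sample",
    "build_corpus",
    "load_corpus",
    "build_fixed_concentration_tests",
    "LibraryRenderer",
]

#: Name under which the quantitative reference enters the composition map.
REFERENCE_NAME = "TSP"
#: TSP-d4 contributes nine equivalent methyl protons.
REFERENCE_PROTONS = 9.0
#: Coupling of the generic 1:2:1 artifact triplet (Hz).
ARTIFACT_TRIPLET_J_HZ = 7.0


@dataclass(frozen=True)
class AugmentationConfig:
    """All nuisance parameters of the augmentation workflow.

    Fractions (``noise_pp_frac``, ``baseline_max_frac``) are relative to the
    reference peak height; ``shift_max_ppb`` is in parts per billion of the
    ppm scale; concentrations in mM.
    """

    noise_pp_frac: float = 0.001        # peak-to-peak noise, ~0.1% of reference
    lf_noise_multiplier: float = 1.0    # 4.0 for the adjusted-SNR variant
    shift_max_ppb: float = 3.4
    baseline_max_frac: float = 0.006
    max_singlets: int = 3
    max_triplets: int = 3
    include_triplets: bool = True
    dropout_prob: float = 0.5
    conc_lo: float = 1.0
    conc_hi: float = 50.0
    ref_conc: float = 2.96

    def __post_init__(self) -> None:
        if self.noise_pp_frac < 0:
            raise ValidationError(f"noise_pp_frac must be >= 0, got {self.noise_pp_frac}")
        if self.lf_noise_multiplier < 1:
            raise ValidationError(
                f"lf_noise_multiplier must be >= 1, got {self.lf_noise_multiplier}"
            )
        if not 0 <= self.dropout_prob <= 1:
            raise ValidationError(f"dropout_prob must be in [0, 1], got {self.dropout_prob}")
        if self.conc_lo > self.conc_hi:
            raise ValidationError(
                f"conc_lo ({self.conc_lo}) must not exceed conc_hi ({self.conc_hi})"
            )
        if self.max_singlets < 0 or self.max_triplets < 0:
            raise ValidationError("max_singlets and max_triplets must be >= 0")
        if self.shift_max_ppb < 0 or self.baseline_max_frac < 0:
            raise ValidationError("shift_max_ppb and baseline_max_frac must be >= 0")

    @property
    def reference_height(self) -> float:
        """Analytic peak height of the reference singlet (normalizer)."""
        return self.ref_conc * REFERENCE_PROTONS


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus layout: sample counts, split, seed, fields, and grid."""

    n_all_present: int = 10_000
    n_with_dropout: int = 10_000
    train_count: int = 16_000
    val_count: int = 4_000
    test_count: int = 100
    seed: int = 0
    lf_freq: float = LF_FREQ_MHZ
    hf_freq: float = HF_FREQ_MHZ
    n_points: int = DEFAULT_N_POINTS
    ppm_min: float = DEFAULT_PPM_MIN
    ppm_max: float = DEFAULT_PPM_MAX

    def __post_init__(self) -> None:
        if self.train_count + self.val_count != self.n_all_present + self.n_with_dropout:
            raise ValidationError(
                f"train_count + val_count ({self.train_count + self.val_count}) must equal "
                f"n_all_present + n_with_dropout ({self.n_all_present + self.n_with_dropout})"
            )
        if min(self.n_all_present, self.n_with_dropout, self.train_count,
               self.val_count, self.test_count) < 0:
            raise ValidationError("all corpus counts must be >= 0")

    def lf_axis(self) -> SpectralAxis:
        return make_axis(self.n_points, self.ppm_min, self.ppm_max, self.lf_freq)

    def hf_axis(self) -> SpectralAxis:
        return make_axis(self.n_points, self.ppm_min, self.ppm_max, self.hf_freq)


@dataclass
class PairedSample:
    """One mixture at both fields plus its concentration label vector."""

    lf: SpectrumRecord
    hf: SpectrumRecord
    conc: np.ndarray  # mM per library metabolite (0 when dropped out)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=np.float64)
        if self.lf.composition != self.hf.composition:
            raise ValidationError("paired LF/HF spectra must share one composition")


# ---------------------------------------------------------------------------
# Single augmentation steps
# ---------------------------------------------------------------------------


def draw_composition(
    library: Sequence[MetaboliteSpinModel],
    cfg: AugmentationConfig,
    use_dropout: bool,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw per-metabolite concentrations ~ Uniform(conc_lo, conc_hi).

    With ``use_dropout`` each metabolite is independently omitted with
    probability ``cfg.dropout_prob``.
    """
    comp: dict[str, float] = {}
    for model in library:
        conc = float(rng.uniform(cfg.conc_lo, cfg.conc_hi))
        if use_dropout and rng.random() < cfg.dropout_prob:
            continue
        comp[model.name] = conc
    return comp


def add_reference(spec: SpectrumRecord, cfg: AugmentationConfig) -> SpectrumRecord:
    """Add the quantitative reference singlet at 0.0 ppm."""
    if REFERENCE_NAME in spec.composition:
        raise ValidationError("reference already present in composition")
    out = spec.copy()
    ref = Multiplet(0.0, (), REFERENCE_PROTONS)
    render_multiplet(ref, out.axis, cfg.ref_conc, out=out.intensities)
    out.composition[REFERENCE_NAME] = cfg.ref_conc
    return out


def add_noise(
    spec: SpectrumRecord,
    cfg: AugmentationConfig,
    multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> SpectrumRecord:
    """Add i.i.d. uniform noise with peak-to-peak amplitude
    ``multiplier x noise_pp_frac x reference height``."""
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be positive, got {multiplier}")
    if rng is None:
        rng = np.random.default_rng()
    a = multiplier * cfg.noise_pp_frac * cfg.reference_height
    out = spec.copy()
    out.intensities = out.intensities + rng.uniform(-a / 2.0, a / 2.0, spec.axis.n_points)
    out.provenance["noise_pp_amplitude"] = a
    return out


def draw_jitter_ppm(cfg: AugmentationConfig, rng: np.random.Generator) -> float:
    """One signed chemical-shift jitter in ppm, |delta| <= shift_max_ppb."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * rng.uniform(0.0, cfg.shift_max_ppb) * 1e-3


def _translate(y: np.ndarray, shift: int) -> np.ndarray:
    """Translate by an integer number of grid points, zero-filling the edges."""
    if shift == 0:
        return y.copy()
    out = np.zeros_like(y)
    if shift > 0:
        out[shift:] = y[:-shift]
    else:
        out[:shift] = y[-shift:]
    return out


def jitter_metabolite(
    component: SpectrumRecord,
    cfg: AugmentationConfig,
    rng: np.random.Generator | None = None,
    delta_ppm: float | None = None,
) -> SpectrumRecord:
    """Shift a single metabolite's component spectrum by a small random ppm.

    The shift is realized as a nearest-integer grid translation (avoiding
    interpolation artifacts); vacated edge points are zero-filled.  Pass
    ``delta_ppm`` to reuse one draw across the two field renderings.
    """
    if delta_ppm is None:
        if rng is None:
            rng = np.random.default_rng()
        delta_ppm = draw_jitter_ppm(cfg, rng)
    shift = int(round(delta_ppm / component.axis.delta_ppm))
    out = component.copy()
    out.intensities = _translate(out.intensities, shift)
    out.provenance["jitter_ppm"] = delta_ppm
    out.provenance["jitter_points"] = shift
    return out


def shift_baseline(
    spec: SpectrumRecord,
    cfg: AugmentationConfig,
    rng: np.random.Generator | None = None,
    offset: float | None = None,
) -> SpectrumRecord:
    """Add a constant baseline offset ~ +-Uniform(0, baseline_max_frac x ref height)."""
    if offset is None:
        if rng is None:
            rng = np.random.default_rng()
        sign = 1.0 if rng.random() < 0.5 else -1.0
        offset = sign * rng.uniform(0.0, cfg.baseline_max_frac * cfg.reference_height)
    out = spec.copy()
    out.intensities = out.intensities + offset
    out.provenance["baseline_offset"] = offset
    return out


def draw_artifacts(
    cfg: AugmentationConfig,
    ppm_min: float,
    ppm_max: float,
    rng: np.random.Generator,
) -> list[tuple[str, float, float]]:
    """Draw the artifact set: up to ``max_singlets`` singlets and (iff
    ``include_triplets``) up to ``max_triplets`` 1:2:1 triplets, each at a
    uniform random chemical shift with amplitude ~ Uniform(conc_lo, conc_hi)
    in concentration-equivalent units.  Returns (kind, center_ppm, amp)."""
    artifacts: list[tuple[str, float, float]] = []
    k_s = int(rng.integers(0, cfg.max_singlets + 1))
    for _ in range(k_s):
        artifacts.append(("singlet", float(rng.uniform(ppm_min, ppm_max)),
                          float(rng.uniform(cfg.conc_lo, cfg.conc_hi))))
    if cfg.include_triplets:
        k_t = int(rng.integers(0, cfg.max_triplets + 1))
        for _ in range(k_t):
            artifacts.append(("triplet", float(rng.uniform(ppm_min, ppm_max)),
                              float(rng.uniform(cfg.conc_lo, cfg.conc_hi))))
    return artifacts


def _artifact_multiplet(kind: str, center_ppm: float) -> Multiplet:
    if kind == "singlet":
        return Multiplet(center_ppm, (), 1.0)
    if kind == "triplet":
        return Multiplet(center_ppm, (ARTIFACT_TRIPLET_J_HZ, ARTIFACT_TRIPLET_J_HZ), 1.0)
    raise ValidationError(f"unknown artifact kind {kind!r}")


def add_artifacts(
    spec: SpectrumRecord,
    cfg: AugmentationConfig,
    freq: float | None = None,
    rng: np.random.Generator | None = None,
    artifacts: Sequence[tuple[str, float, float]] | None = None,
) -> SpectrumRecord:
    """Add random singlet/triplet artifact peaks (field-scaled lineshapes).

    Pass ``artifacts`` (as returned by :func:`draw_artifacts`) to reuse one
    draw across both field renderings; otherwise a fresh set is drawn.
    """
    ax = spec.axis if freq is None else spec.axis.with_freq(freq)
    if artifacts is None:
        if rng is None:
            rng = np.random.default_rng()
        artifacts = draw_artifacts(cfg, ax.ppm_min, ax.ppm_max, rng)
    out = spec.copy()
    for kind, center, amp in artifacts:
        render_multiplet(_artifact_multiplet(kind, center), ax, amp, out=out.intensities)
    out.provenance["artifacts"] = list(artifacts)
    return out


# ---------------------------------------------------------------------------
# Paired-sample generation
# ---------------------------------------------------------------------------


class LibraryRenderer:
    """Caches unit-concentration component spectra of a library at one field.

    Mixture assembly then reduces to concentration-weighted sums of integer
    translations of the cached rows, which keeps corpus generation cheap.
    """

    def __init__(self, library: Sequence[MetaboliteSpinModel], axis: SpectralAxis):
        self.library = tuple(library)
        self.axis = axis
        self.names = [m.name for m in self.library]
        self.unit = np.stack(
            [render_metabolite(m, axis, 1.0).intensities for m in self.library]
        ) if self.library else np.zeros((0, axis.n_points))

    def mixture(
        self, composition: Mapping[str, float], jitter_ppm: Mapping[str, float] | None = None
    ) -> np.ndarray:
        y = np.zeros(self.axis.n_points)
        for i, name in enumerate(self.names):
            conc = composition.get(name, 0.0)
            if conc == 0.0:
                continue
            comp = self.unit[i]
            if jitter_ppm:
                shift = int(round(jitter_ppm.get(name, 0.0) / self.axis.delta_ppm))
                comp = _translate(comp, shift)
            y += conc * comp
        return y


def generate_paired_sample(
    library: Sequence[MetaboliteSpinModel],
    aug: AugmentationConfig,
    corpus: CorpusConfig,
    use_dropout: bool,
    rng: np.random.Generator,
    renderers: tuple[LibraryRenderer, LibraryRenderer] | None = None,
) -> PairedSample:
    """Generate one mixture rendered at both fields.

    Composition, per-metabolite jitters (in ppm), the artifact set, and the
    baseline offset are drawn once and shared; noise is drawn independently
    per field (LF first), with the LF amplitude scaled by
    ``aug.lf_noise_multiplier``.
    """
    if renderers is None:
        renderers = (
            LibraryRenderer(library, corpus.lf_axis()),
            LibraryRenderer(library, corpus.hf_axis()),
        )
    lf_r, hf_r = renderers
    comp = draw_composition(library, aug, use_dropout, rng)
    jitters = {name: draw_jitter_ppm(aug, rng) for name in comp}
    artifacts = draw_artifacts(aug, corpus.ppm_min, corpus.ppm_max, rng)
    baseline_sign = 1.0 if rng.random() < 0.5 else -1.0
    baseline = baseline_sign * rng.uniform(0.0, aug.baseline_max_frac * aug.reference_height)

    records = []
    for rend, mult in ((lf_r, aug.lf_noise_multiplier), (hf_r, 1.0)):
        rec = SpectrumRecord(
            rend.axis,
            rend.mixture(comp, jitters),
            composition=dict(comp),
            provenance={"field_mhz": rend.axis.spectrometer_freq, "jitters_ppm": dict(jitters)},
        )
        rec = add_reference(rec, aug)
        rec = add_artifacts(rec, aug, artifacts=artifacts)
        rec = shift_baseline(rec, aug, offset=baseline)
        rec = add_noise(rec, aug, multiplier=mult, rng=rng)
        records.append(rec)
    lf, hf = records
    conc = np.array([comp.get(m.name, 0.0) for m in library])
    return PairedSample(lf=lf, hf=hf, conc=conc)


# ---------------------------------------------------------------------------
# Corpus building and persistence
# ---------------------------------------------------------------------------


def _h5_create(group: h5py.Group, name: str, data: np.ndarray) -> None:
    # track_times=False keeps corpus files byte-identical across reruns
    group.create_dataset(name, data=data, track_times=False)


def build_corpus(
    library: Sequence[MetaboliteSpinModel],
    aug: AugmentationConfig,
    corpus: CorpusConfig,
    path: str | Path,
) -> dict:
    """Generate and persist a full paired corpus to one HDF5 container.

    Layout: ``/train/lf``, ``/train/hf``, ``/train/conc``, same under
    ``/val`` and ``/test`` (float32 spectra, float64 labels), plus a JSON
    manifest in the root attributes.  The first ``n_all_present`` samples are
    generated without dropout and the next ``n_with_dropout`` with dropout;
    train/val membership is a seed-determined shuffle of those indices.  Test
    samples are generated all-present, as held-out mixtures.  Returns the
    manifest dict.
    """
    path = Path(path)
    rng = np.random.default_rng(corpus.seed)
    renderers = (
        LibraryRenderer(library, corpus.lf_axis()),
        LibraryRenderer(library, corpus.hf_axis()),
    )
    n_total = corpus.n_all_present + corpus.n_with_dropout
    n_pts, n_met = corpus.n_points, len(library)

    lf = np.empty((n_total, n_pts), dtype=np.float32)
    hf = np.empty((n_total, n_pts), dtype=np.float32)
    conc = np.empty((n_total, n_met), dtype=np.float64)
    for i in range(n_total):
        sample = generate_paired_sample(
            library, aug, corpus, use_dropout=(i >= corpus.n_all_present),
            rng=rng, renderers=renderers,
        )
        lf[i], hf[i], conc[i] = sample.lf.intensities, sample.hf.intensities, sample.conc

    perm = rng.permutation(n_total)
    tr, va = perm[: corpus.train_count], perm[corpus.train_count:]

    test_lf = np.empty((corpus.test_count, n_pts), dtype=np.float32)
    test_hf = np.empty((corpus.test_count, n_pts), dtype=np.float32)
    test_conc = np.empty((corpus.test_count, n_met), dtype=np.float64)
    for i in range(corpus.test_count):
        sample = generate_paired_sample(
            library, aug, corpus, use_dropout=False, rng=rng, renderers=renderers
        )
        test_lf[i], test_hf[i], test_conc[i] = (
            sample.lf.intensities, sample.hf.intensities, sample.conc,
        )

    manifest = {
        "format": "fieldlift-corpus-v1",
        "package_version": __version__,
        "augmentation": asdict(aug),
        "corpus": asdict(corpus),
        "seed": corpus.seed,
        "library_hash": library_hash(library),
        "metabolites": [m.name for m in library],
    }
    with h5py.File(path, "w", track_order=False) as fh:
        for split, idx in (("train", tr), ("val", va)):
            g = fh.create_group(split)
            _h5_create(g, "lf", lf[idx])
            _h5_create(g, "hf", hf[idx])
            _h5_create(g, "conc", conc[idx])
        g = fh.create_group("test")
        _h5_create(g, "lf", test_lf)
        _h5_create(g, "hf", test_hf)
        _h5_create(g, "conc", test_conc)
        fh.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
    return manifest


def load_corpus(path: str | Path) -> dict:
    """Load a corpus container into memory.

    Returns ``{"train": {"lf", "hf", "conc"}, "val": ..., "test": ...,
    "manifest": dict}``; spectra come back in their float32 storage dtype,
    concentration labels as float64.
    """
    out: dict = {}
    with h5py.File(path, "r") as fh:
        for split in ("train", "val", "test"):
            out[split] = {
                k: np.asarray(fh[split][k],
                              dtype=np.float64 if k == "conc" else np.float32)
                for k in fh[split]
            }
        out["manifest"] = json.loads(fh.attrs["manifest"])
    return out


def build_fixed_concentration_tests(
    library: Sequence[MetaboliteSpinModel],
    aug: AugmentationConfig,
    levels: Sequence[float],
    corpus: CorpusConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[PairedSample]:
    """Fixed-concentration quantification test spectra.

    One paired sample per level with *every* library metabolite at that
    concentration; no dropout, no jitter, and no artifacts beyond the
    reference.  "Mean intensity noise" is realized as a single noise draw at
    the default amplitude (per-field, LF scaled by ``lf_noise_multiplier``).
    Set ``aug.noise_pp_frac`` to zero for noiseless variants.
    """
    if len(levels) == 0:
        raise ValidationError("levels must be non-empty")
    corpus = corpus or CorpusConfig()
    if rng is None:
        rng = np.random.default_rng(corpus.seed)
    renderers = (
        LibraryRenderer(library, corpus.lf_axis()),
        LibraryRenderer(library, corpus.hf_axis()),
    )
    samples = []
    for level in levels:
        if not 0 <= level <= aug.conc_hi:
            warnings.warn(
                f"concentration level {level} mM outside [0, {aug.conc_hi}] mM",
                stacklevel=2,
            )
        comp = {m.name: float(level) for m in library}
        records = []
        for rend, mult in ((renderers[0], aug.lf_noise_multiplier), (renderers[1], 1.0)):
            rec = SpectrumRecord(
                rend.axis,
                rend.mixture(comp),
                composition=dict(comp),
                provenance={"field_mhz": rend.axis.spectrometer_freq, "level_mm": level},
            )
            rec = add_reference(rec, aug)
            if aug.noise_pp_frac > 0:
                rec = add_noise(rec, aug, multiplier=mult, rng=rng)
            records.append(rec)
        samples.append(
            PairedSample(records[0], records[1], np.full(len(library), float(level)))
        )
    return samples
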
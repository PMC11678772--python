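"""Spectral axes, parametric metabolite spin models, and field-dependent rendering.

A 1D :sup:`1`\\ H NMR spectrum is modelled in the frequency domain as a sum of
Lorentzian lines.  Chemical shifts are stored in ppm (field independent),
scalar couplings in Hz (field independent), so the *ppm* splitting and the
*ppm* linewidth of a multiplet both shrink by the ratio of spectrometer
frequencies when the same spin system is rendered at a higher field.  That
4x resolution gain between 100 MHz (benchtop) and 400 MHz instruments is the
physical basis of the low-field -> high-field conversion task this package
implements.

Amplitude convention
--------------------
A 1-proton singlet at 1 mM with a 1.0 Hz linewidth has unit peak height
(at 400 MHz, and — because Lorentzian peak height is invariant under the
ppm-axis rescaling that a field change induces — at any field).  All other
amplitudes follow by linearity in concentration and proton count.

Storage convention: intensities are kept in ascending-ppm order; display
layers may reverse to the NMR convention (high ppm on the left).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "ParseError",
    "SpectralAxis",
    "Multiplet",
    "MetaboliteSpinModel",
    "SpectrumRecord",
    "make_axis",
    "multiplet_line_positions",
    "render_multiplet",
    "render_metabolite",
    "write_spectrum",
    "read_external_spectrum",
    "read_peaklist",
    "builtin_library",
    "extended_library",
    "library_hash",
    "LF_FREQ_MHZ",
    "HF_FREQ_MHZ",
    "DEFAULT_N_POINTS",
    "DEFAULT_PPM_MIN",
    "DEFAULT_PPM_MAX",
    "DEFAULT_LINEWIDTH_HZ",
]

#: Proton Larmor frequencies of the two instruments being compared (MHz).
LF_FREQ_MHZ = 100.0
HF_FREQ_MHZ = 400.0

#: Standard acquisition window: 46,000 points from -0.32 to 10.2 ppm.
DEFAULT_N_POINTS = 46_000
DEFAULT_PPM_MIN = -0.32
DEFAULT_PPM_MAX = 10.2

#: Default full width at half maximum for synthetic lines (Hz).
DEFAULT_LINEWIDTH_HZ = 1.0


class ValidationError(ValueError):
    """A domain object was constructed with out-of-range fields."""


class FormatError(ValueError):
    """A spectrum file is structurally valid but lacks required metadata."""


class ParseError(ValueError):
    """A spectrum file could not be parsed; message carries line context."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform chemical-shift grid tied to a spectrometer frequency.

    Parameters
    ----------
    n_points
        Number of grid points (>= 2).
    ppm_min, ppm_max
        Window bounds in ppm, ``ppm_max > ppm_min``.
    spectrometer_freq
        Proton Larmor frequency in MHz (> 0).
    """

    n_points: int
    ppm_min: float
    ppm_max: float
    spectrometer_freq: float

    def __post_init__(self) -> None:
        if int(self.n_points) != self.n_points or self.n_points < 2:
            raise ValidationError(f"n_points must be an integer >= 2, got {self.n_points}")
        if not self.ppm_max > self.ppm_min:
            raise ValidationError(
                f"inverted bounds: ppm_max ({self.ppm_max}) must exceed ppm_min ({self.ppm_min})"
            )
        if not self.spectrometer_freq > 0:
            raise ValidationError(
                f"spectrometer_freq must be positive, got {self.spectrometer_freq}"
            )

    @property
    def delta_ppm(self) -> float:
        """Uniform grid spacing in ppm."""
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)

    @cached_property
    def ppm(self) -> np.ndarray:
        """Grid positions in ascending ppm order (read-only)."""
        grid = np.linspace(self.ppm_min, self.ppm_max, self.n_points)
        grid.setflags(write=False)
        return grid

    def hz_offset(self, i: int | np.ndarray) -> float | np.ndarray:
        """Frequency offset of grid index ``i`` in Hz: ppm(i) x MHz."""
        return self.ppm[i] * self.spectrometer_freq

    def index_of(self, ppm: float) -> int:
        """Index of the grid point nearest ``ppm``."""
        return int(round((ppm - self.ppm_min) / self.delta_ppm))

    def with_freq(self, freq: float) -> "SpectralAxis":
        """Same grid, different spectrometer frequency."""
        return SpectralAxis(self.n_points, self.ppm_min, self.ppm_max, freq)


@dataclass(frozen=True)
class Multiplet:
    """One chemically equivalent proton group: a first-order multiplet.

    ``j_hz`` lists the scalar couplings in Hz; n identical couplings give the
    familiar n+1 lines with binomial intensities (doublet, 1:2:1 triplet, ...).
    ``protons`` is the relative integral carried by the whole multiplet and
    ``linewidth_hz`` the Lorentzian full width at half maximum in Hz.
    """

    center_ppm: float
    j_hz: tuple[float, ...] = ()
    protons: float = 1.0
    linewidth_hz: float = DEFAULT_LINEWIDTH_HZ

    def __init__(
        self,
        center_ppm: float,
        j_hz: Sequence[float] = (),
        protons: float = 1.0,
        linewidth_hz: float = DEFAULT_LINEWIDTH_HZ,
    ) -> None:
        object.__setattr__(self, "center_ppm", float(center_ppm))
        object.__setattr__(self, "j_hz", tuple(float(j) for j in j_hz))
        object.__setattr__(self, "protons", float(protons))
        object.__setattr__(self, "linewidth_hz", float(linewidth_hz))
        if not self.protons > 0:
            raise ValidationError(f"protons must be positive, got {protons}")
        if not self.linewidth_hz > 0:
            raise ValidationError(f"linewidth_hz must be positive, got {linewidth_hz}")
        if any(j < 0 for j in self.j_hz):
            raise ValidationError(f"all j_hz must be >= 0, got {j_hz}")


@dataclass(frozen=True)
class MetaboliteSpinModel:
    """Named collection of multiplets standing in for one compound's spectrum."""

    name: str
    multiplets: tuple[Multiplet, ...]

    def __init__(self, name: str, multiplets: Sequence[Multiplet]) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "multiplets", tuple(multiplets))
        if not self.name:
            raise ValidationError("name must be non-empty")
        if not self.multiplets:
            raise ValidationError(f"metabolite {name!r} needs at least one multiplet")

    @property
    def total_protons(self) -> float:
        return sum(m.protons for m in self.multiplets)


@dataclass
class SpectrumRecord:
    """One rendered spectrum: intensities on an axis plus its composition.

    ``composition`` maps metabolite name to concentration in mM;
    ``provenance`` is free-form metadata (field, seed, augmentation draws).
    """

    axis: SpectralAxis
    intensities: np.ndarray
    composition: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != (self.axis.n_points,):
            raise ValidationError(
                f"intensities length {self.intensities.shape} does not match "
                f"axis.n_points {self.axis.n_points}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    def copy(self) -> "SpectrumRecord":
        return SpectrumRecord(
            self.axis,
            self.intensities.copy(),
            dict(self.composition),
            dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# Construction and rendering
# ---------------------------------------------------------------------------


def make_axis(
    n_points: int = DEFAULT_N_POINTS,
    ppm_min: float = DEFAULT_PPM_MIN,
    ppm_max: float = DEFAULT_PPM_MAX,
    freq: float = HF_FREQ_MHZ,
) -> SpectralAxis:
    """Build a uniform ppm axis; defaults give the standard 46,000-point window."""
    return SpectralAxis(n_points, ppm_min, ppm_max, freq)


def multiplet_line_positions(m: Multiplet, freq: float) -> list[tuple[float, float]]:
    """First-order stick pattern of a multiplet at a given field.

    Each coupling J splits every line in two at +-J/(2 freq) ppm.  Coincident
    lines merge with summed weights; weights are normalized to sum to
    ``m.protons``.  Returns ``[(ppm, weight), ...]`` sorted by position.
    """
    if not freq > 0:
        raise ValidationError(f"freq must be positive, got {freq}")
    offsets = np.array([0.0])
    weights = np.array([1.0])
    for j in m.j_hz:
        half = j / (2.0 * freq)  # Hz -> ppm
        offsets = np.concatenate([offsets - half, offsets + half])
        weights = np.concatenate([weights, weights]) / 2.0
    # merge numerically coincident lines (identical couplings give exact ties)
    order = np.argsort(offsets, kind="stable")
    offsets, weights = offsets[order], weights[order]
    merged: list[tuple[float, float]] = []
    tol = 1e-12
    for off, w in zip(offsets, weights):
        if merged and abs(off - merged[-1][0]) <= tol:
            merged[-1] = (merged[-1][0], merged[-1][1] + w)
        else:
            merged.append((off, w))
    scale = m.protons  # weights currently sum to 1
    return [(m.center_ppm + off, w * scale) for off, w in merged]


def _add_lorentzian(
    out: np.ndarray, axis: SpectralAxis, center_ppm: float, height: float, fwhm_ppm: float
) -> None:
    """Accumulate a peak-height-normalized Lorentzian into ``out`` in place."""
    hw = fwhm_ppm / 2.0
    d = axis.ppm - center_ppm
    out += height * hw * hw / (d * d + hw * hw)


def render_multiplet(
    m: Multiplet, axis: SpectralAxis, conc: float, out: np.ndarray | None = None
) -> np.ndarray:
    """Render one multiplet at concentration ``conc`` (mM) onto ``axis``."""
    if out is None:
        out = np.zeros(axis.n_points)
    fwhm_ppm = m.linewidth_hz / axis.spectrometer_freq
    for pos, w in multiplet_line_positions(m, axis.spectrometer_freq):
        _add_lorentzian(out, axis, pos, conc * w, fwhm_ppm)
    return out


def render_metabolite(
    model: MetaboliteSpinModel, axis: SpectralAxis, conc: float
) -> SpectrumRecord:
    """Render a metabolite's full spin model at concentration ``conc`` (mM).

    The result is a sum of Lorentzians, one per stick line, with peak height
    ``conc x line_weight`` (the unit-height amplitude convention) and ppm
    FWHM ``linewidth_hz / spectrometer_freq``.  Linear in ``conc``.
    """
    if conc < 0:
        raise ValidationError(f"conc must be >= 0, got {conc}")
    y = np.zeros(axis.n_points)
    for m in model.multiplets:
        render_multiplet(m, axis, conc, out=y)
    return SpectrumRecord(
        axis,
        y,
        composition={model.name: float(conc)},
        provenance={"field_mhz": axis.spectrometer_freq, "source": "render_metabolite"},
    )


# ---------------------------------------------------------------------------
# File IO: package writer, JCAMP-DX reader, TSV peak lists
# ---------------------------------------------------------------------------


def write_spectrum(record: SpectrumRecord, path: str | Path) -> None:
    """Write a spectrum as a minimal JCAMP-DX (##XYPOINTS) file.

    Values are written at full float precision so that reading the file back
    onto the same axis reproduces the intensities exactly.
    """
    path = Path(path)
    ax = record.axis
    lines = [
        "##TITLE=fieldlift spectrum",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY",
        f"##.OBSERVE FREQUENCY={float(ax.spectrometer_freq)!r}",
        f"##NPOINTS={ax.n_points}",
        f"##$COMPOSITION={json.dumps(record.composition)}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [
        f"{float(x)!r}, {float(y)!r}" for x, y in zip(ax.ppm, record.intensities)
    ]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


_LDR_RE = re.compile(r"^##(?P<label>[^=]*)=(?P<value>.*)$")
_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _parse_jcamp(path: Path) -> dict:
    """Parse a JCAMP-DX file into labels plus (x, y) arrays.

    Supports ##XYPOINTS / ##PEAK TABLE ``(XY..XY)`` pair tables and
    ##XYDATA ``(X++(Y..Y))`` with FIRSTX/LASTX/XFACTOR/YFACTOR.
    """
    labels: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    mode: str | None = None
    table_label = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            m = _LDR_RE.match(line)
            if m:
                label = m.group("label").strip().upper()
                value = m.group("value").strip()
                if label == "END":
                    mode = None
                    continue
                if label in ("XYPOINTS", "PEAK TABLE", "PEAKTABLE"):
                    mode, table_label = "pairs", label
                    continue
                if label == "XYDATA":
                    mode, table_label = "xydata", label
                    continue
                mode = None
                labels[label] = value
                continue
            if mode is None:
                continue
            nums = [float(t) for t in _NUM_RE.findall(line)]
            if mode == "pairs":
                if len(nums) % 2 != 0:
                    raise ParseError(
                        f"{path.name}:{lineno}: odd number of values in "
                        f"##{table_label} row: {line!r}"
                    )
                xs.extend(nums[0::2])
                ys.extend(nums[1::2])
            else:  # xydata: leading X then a run of Y values
                if len(nums) < 2:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected 'x y1 y2 ...' in ##XYDATA, got {line!r}"
                    )
                xf = float(labels.get("XFACTOR", 1.0))
                yf = float(labels.get("YFACTOR", 1.0))
                x0 = nums[0] * xf
                yrun = [v * yf for v in nums[1:]]
                if "DELTAX" in labels:
                    dx = float(labels["DELTAX"])
                elif "FIRSTX" in labels and "LASTX" in labels and "NPOINTS" in labels:
                    n = int(float(labels["NPOINTS"]))
                    dx = (float(labels["LASTX"]) - float(labels["FIRSTX"])) / max(n - 1, 1)
                else:
                    raise FormatError(
                        f"{path.name}: ##XYDATA needs DELTAX or FIRSTX/LASTX/NPOINTS"
                    )
                xs.extend(x0 + dx * np.arange(len(yrun)))
                ys.extend(yrun)
    if not xs:
        raise ParseError(f"{path.name}: no ##XYPOINTS/##XYDATA/##PEAK TABLE data found")
    return {"labels": labels, "x": np.asarray(xs), "y": np.asarray(ys),
            "is_peak_table": table_label in ("PEAK TABLE", "PEAKTABLE")}


def read_external_spectrum(path: str | Path, axis: SpectralAxis) -> SpectrumRecord:
    """Read a JCAMP-DX spectrum and resample it onto ``axis``.

    The source ppm axis may be stored ascending or descending; points of the
    target axis outside the source range are set to zero.  Files whose x axis
    is in Hz require an ``##.OBSERVE FREQUENCY`` label for the ppm conversion;
    its absence is a :class:`FormatError`.  Peak tables are deposited onto the
    nearest grid points rather than interpolated.
    """
    path = Path(path)
    parsed = _parse_jcamp(path)
    labels = parsed["labels"]
    x, y = parsed["x"], parsed["y"]
    xunits = labels.get("XUNITS", "").upper()
    freq = labels.get(".OBSERVE FREQUENCY") or labels.get("$FREQUENCY")
    if xunits in ("HZ", "HERTZ"):
        if freq is None:
            raise FormatError(
                f"{path.name}: x axis is in Hz but '.OBSERVE FREQUENCY' is missing"
            )
        x = x / float(freq)
    elif xunits != "PPM":
        raise FormatError(
            f"{path.name}: missing or unsupported XUNITS ({xunits or 'absent'}); "
            "need PPM or HZ"
        )
    if freq is None:
        raise FormatError(f"{path.name}: missing '.OBSERVE FREQUENCY' metadata")
    if parsed["is_peak_table"]:
        out = np.zeros(axis.n_points)
        for xi, yi in zip(x, y):
            idx = axis.index_of(xi)
            if 0 <= idx < axis.n_points:
                out[idx] += yi
    else:
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        out = np.interp(axis.ppm, xs, ys, left=0.0, right=0.0)
        # np.interp clamps at the edges; zero strictly outside the source range
        out[axis.ppm < xs[0]] = 0.0
        out[axis.ppm > xs[-1]] = 0.0
    composition = {}
    if "$COMPOSITION" in labels:
        composition = {k: float(v) for k, v in json.loads(labels["$COMPOSITION"]).items()}
    return SpectrumRecord(
        axis,
        out,
        composition=composition,
        provenance={
            "source_file": str(path),
            "source_points": int(x.size),
            "source_ppm_range": (float(np.min(x)), float(np.max(x))),
        },
    )


def read_peaklist(path: str | Path, name: str | None = None) -> MetaboliteSpinModel:
    """Read the package's tab-separated peak-list format.

    Columns (tab separated): ``center_ppm``, ``j_hz`` (comma-separated Hz
    list, empty for a singlet), ``protons``, and optionally ``linewidth_hz``.
    Lines starting with ``#`` are comments; a ``# name: <id>`` comment sets
    the metabolite name (default: the file stem).
    """
    path = Path(path)
    model_name = name or path.stem
    multiplets: list[Multiplet] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*name\s*:\s*(\S+)", line)
            if m:
                model_name = m.group(1)
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ParseError(
                f"{path.name}:{lineno}: expected 'ppm<TAB>j_list<TAB>protons', got {raw!r}"
            )
        try:
            center = float(parts[0])
            js = tuple(float(j) for j in parts[1].split(",") if j.strip())
            protons = float(parts[2])
            lw = float(parts[3]) if len(parts) > 3 and parts[3] else DEFAULT_LINEWIDTH_HZ
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
        multiplets.append(Multiplet(center, js, protons, lw))
    if not multiplets:
        raise ParseError(f"{path.name}: no peaks found")
    return MetaboliteSpinModel(model_name, multiplets)


# ---------------------------------------------------------------------------
# Built-in synthetic metabolite library
# ---------------------------------------------------------------------------

# Procedurally specified stand-ins for per-metabolite simulated reference
# spectra, so the full pipeline runs without any external downloads.  Shifts
# (0.5-9.5 ppm), couplings (2-12 Hz), and proton counts were drawn once and
# are frozen here as versioned constants; linewidths are 1.0 Hz.  Names follow
# the 21-compound mixture panel the workflow targets; the multiplet patterns
# are synthetic, not literature values.
_BUILTIN_LIBRARY: tuple[MetaboliteSpinModel, ...] = (
    MetaboliteSpinModel("maleic_acid", (Multiplet(4.549, [7.19, 8.69], 1), Multiplet(2.493, [5.56, 5.56, 5.56], 1))),
    MetaboliteSpinModel("histidine", (Multiplet(8.672, [4.24, 4.24, 4.24], 3), Multiplet(1.499, [5.46, 5.46, 5.46], 3), Multiplet(8.943, [7.09, 7.09, 7.09], 4), Multiplet(9.491, [], 3))),
    MetaboliteSpinModel("1_methylhistidine", (Multiplet(3.332, [], 1), Multiplet(7.79, [], 2), Multiplet(6.441, [], 1))),
    MetaboliteSpinModel("acetic_acid", (Multiplet(4.493, [2.87, 10.48], 3), Multiplet(8.091, [], 1), Multiplet(4.914, [10.18], 1), Multiplet(6.32, [3.67], 3))),
    MetaboliteSpinModel("creatine", (Multiplet(1.588, [2.91], 1),)),
    MetaboliteSpinModel("glycine", (Multiplet(4.726, [5.14, 11.38], 4),)),
    MetaboliteSpinModel("formic_acid", (Multiplet(5.493, [2.62], 1), Multiplet(1.375, [], 3), Multiplet(9.075, [], 3))),
    MetaboliteSpinModel("hypoxanthine", (Multiplet(5.877, [8.91, 8.91], 1), Multiplet(7.554, [], 3))),
    MetaboliteSpinModel("l_alanine", (Multiplet(7.618, [], 2), Multiplet(2.044, [9.55, 9.92], 4), Multiplet(9.088, [], 1), Multiplet(3.311, [3.01], 4))),
    MetaboliteSpinModel("lysine", (Multiplet(2.206, [2.02, 2.02, 2.02], 3),)),
    MetaboliteSpinModel("lactic_acid", (Multiplet(5.621, [3.57], 1), Multiplet(1.613, [9.17, 11.05], 4), Multiplet(9.406, [], 3), Multiplet(5.864, [], 2))),
    MetaboliteSpinModel("inosine", (Multiplet(4.522, [4.38, 4.38, 4.38], 2), Multiplet(8.755, [], 2), Multiplet(1.762, [], 2))),
    MetaboliteSpinModel("pyruvic_acid", (Multiplet(2.836, [2.1, 2.1], 2), Multiplet(8.504, [3.65, 5.03], 3))),
    MetaboliteSpinModel("succinic_acid", (Multiplet(6.318, [9.72, 10.66], 4), Multiplet(1.299, [7.47], 2))),
    MetaboliteSpinModel("xanthine", (Multiplet(5.433, [6.39, 8.11], 4), Multiplet(1.716, [], 3), Multiplet(0.744, [], 3), Multiplet(6.248, [2.49], 4))),
    MetaboliteSpinModel("creatinine", (Multiplet(8.527, [], 4), Multiplet(1.917, [], 3))),
    MetaboliteSpinModel("leucine", (Multiplet(5.611, [9.72], 2), Multiplet(0.989, [2.98, 3.17, 7.99], 1), Multiplet(7.478, [], 3))),
    MetaboliteSpinModel("l_valine", (Multiplet(8.832, [], 1), Multiplet(6.71, [], 3), Multiplet(1.668, [], 4), Multiplet(7.152, [], 2))),
    MetaboliteSpinModel("nad", (Multiplet(3.039, [4.92], 3), Multiplet(8.976, [3.16, 9.75], 1), Multiplet(8.627, [7.22], 1), Multiplet(7.489, [], 1))),
    MetaboliteSpinModel("niacinamide", (Multiplet(9.089, [], 3),)),
    MetaboliteSpinModel("alpha_d_glucose", (Multiplet(5.883, [], 4),)),
)


def builtin_library(n: int | None = None) -> tuple[MetaboliteSpinModel, ...]:
    """The built-in synthetic metabolite library (first ``n`` entries if given)."""
    if n is None:
        return _BUILTIN_LIBRARY
    if not 1 <= n <= len(_BUILTIN_LIBRARY):
        raise ValidationError(
            f"n must be in 1..{len(_BUILTIN_LIBRARY)}, got {n}"
        )
    return _BUILTIN_LIBRARY[:n]


def extended_library(n: int, seed: int = 87_0666) -> tuple[MetaboliteSpinModel, ...]:
    """Library of ``n`` metabolites: the built-in 21 plus procedurally drawn
    extras (for large-panel variants, e.g. 87-compound mixtures).

    Extras are drawn from a fixed seed with the same parameter ranges as the
    built-in constants (shifts 0.5-9.5 ppm, J 2-12 Hz, 1-4 multiplets,
    1-4 protons), so any ``n`` defines one versioned library.
    """
    base = list(_BUILTIN_LIBRARY)
    if n <= len(base):
        return tuple(base[:n])
    rng = np.random.default_rng(seed)
    for i in range(len(base), n):
        multiplets = []
        for _ in range(int(rng.integers(1, 5))):
            n_j = int(rng.integers(0, 4))
            js = [round(float(rng.uniform(2.0, 12.0)), 2)] * n_j if (
                n_j >= 2 and rng.random() < 0.5
            ) else sorted(round(float(rng.uniform(2.0, 12.0)), 2) for _ in range(n_j))
            multiplets.append(
                Multiplet(round(float(rng.uniform(0.5, 9.5)), 3), js,
                          int(rng.integers(1, 5)))
            )
        base.append(MetaboliteSpinModel(f"synthetic_{i + 1:03d}", multiplets))
    return tuple(base)


def library_hash(library: Sequence[MetaboliteSpinModel]) -> str:
    """Stable content hash of a metabolite library (for manifests)."""
    canon = [
        (
            m.name,
            [(mu.center_ppm, list(mu.j_hz), mu.protons, mu.linewidth_hz) for mu in m.multiplets],
        )
        for m in library
    ]
    return hashlib.sha256(json.dumps(canon, sort_keys=True).encode()).hexdigest()[:16]
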
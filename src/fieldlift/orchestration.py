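"""End-to-end experiment orchestration: generate -> train -> evaluate.

Named presets cover the study's dataset variants — the base 21-metabolite
corpus, the adjusted-SNR variant (4x noise on the low-field side), the
87-metabolite variant, the no-triplet quantification corpora — plus a
``desk_scale`` protocol: a reduced replication (10 metabolites, 4,600-point
axis, 1,500/300/50 train/val/test, shrunken architectures) sized so the
whole six-architecture comparison and the quantification comparison run in
minutes on one CPU.  Desk-scale epoch caps give each architecture a roughly
equal wall-clock compute budget (convolutional networks cost far more per
epoch on CPU than the chunked transformer), all within the 300-epoch /
patience-25 protocol's limits.

Every run directory receives one manifest recording package version, config
hash, seeds, corpus hash and architecture specs — enough to re-run the
experiment bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .dataset_generator import (
    AugmentationConfig,
    CorpusConfig,
    build_corpus,
    build_fixed_concentration_tests,
    load_corpus,
)
from .evaluation import run_comparison_suite, run_quantification_suite
from .models import (
    CAESpec,
    DAESpec,
    QuantMLPSpec,
    TCNSpec,
    TransformerSpec,
    UNetSpec,
    spec_to_json,
)
from .spectral_core import (
    MetaboliteSpinModel,
    ValidationError,
    builtin_library,
    extended_library,
)
from .training import TrainConfig

__all__ = [
    "RunManifest",
    "Protocol",
    "full_scale_protocol",
    "desk_scale_protocol",
    "PRESETS",
    "run_experiment",
]

#: Quantification levels (mM) of the fixed-concentration test spectra.
QUANT_LEVELS = (5.0, 25.0, 50.0)

CONVERSION_ARCHS = ("DAE", "CAE", "UNET", "UNET_CHUNKS", "TCN", "TRANSFORMER")


@dataclass
class RunManifest:
    """Provenance for one artifact directory (host-independent)."""

    package_version: str
    preset: str
    config_hash: str
    seed: int
    corpus_hash: str = ""
    quant_corpus_hash: str = ""
    architecture_specs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> None:
        (out_dir / "manifest.json").write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True)
        )


@dataclass
class Protocol:
    """Everything one experiment needs: corpora, architectures, training."""

    name: str
    library: tuple[MetaboliteSpinModel, ...]
    aug: AugmentationConfig
    corpus: CorpusConfig
    quant_aug: AugmentationConfig
    quant_corpus: CorpusConfig
    conversion_specs: dict
    train_cfgs: dict[str, TrainConfig]
    mlp_spec: QuantMLPSpec
    mlp_train_cfg: TrainConfig
    desk_scale: bool


def _conversion_specs(input_len: int, *, dae=(2000, 200), transformer=None,
                      n_chunks: int = 46, seed: int = 0) -> dict:
    chunk_len = input_len // n_chunks
    transformer = transformer or dict(d_model=512, n_layers=6, heads=8, ff=2048)
    return {
        "DAE": DAESpec(input_len, dae[0], dae[1], seed=seed),
        "CAE": CAESpec(input_len, seed=seed),
        "UNET": UNetSpec(input_len, seed=seed),
        "UNET_CHUNKS": UNetSpec(input_len, chunked=True, n_chunks=n_chunks, seed=seed),
        "TCN": TCNSpec(input_len, seed=seed),
        "TRANSFORMER": TransformerSpec(
            n_chunks=n_chunks, chunk_len=chunk_len, dropout=0.1, seed=seed,
            **transformer,
        ),
    }


def full_scale_protocol(variant: str = "base", seed: int = 0) -> Protocol:
    """The full-size protocol: 21 (or 87) metabolites, 46,000-point axis,
    20,000 spectra split 16,000:4,000, full architectures, 300 epochs with
    patience 25.  Variants: ``base``, ``adjusted_snr`` (4x LF noise),
    ``met87`` (87 metabolites, 4x LF noise)."""
    if variant == "base":
        library, lf_mult = builtin_library(), 1.0
    elif variant == "adjusted_snr":
        library, lf_mult = builtin_library(), 4.0
    elif variant == "met87":
        library, lf_mult = extended_library(87), 4.0
    else:
        raise ValidationError(f"unknown full-scale variant {variant!r}")
    aug = AugmentationConfig(lf_noise_multiplier=lf_mult)
    corpus = CorpusConfig(seed=seed)
    train = TrainConfig(max_epochs=300, patience=25, seed=seed)
    return Protocol(
        name=f"full_{variant}",
        library=library,
        aug=aug,
        corpus=corpus,
        quant_aug=replace(aug, include_triplets=False),
        quant_corpus=corpus,
        conversion_specs=_conversion_specs(46_000, seed=seed),
        train_cfgs={a: train for a in CONVERSION_ARCHS},
        mlp_spec=QuantMLPSpec(46_000, 200, len(library), seed=seed),
        mlp_train_cfg=replace(train, task="quantification"),
        desk_scale=False,
    )


#: Desk-scale per-architecture epoch caps: roughly equal wall-clock budgets
#: on one CPU (stride-1 convolutions over the full axis are ~25x costlier
#: per epoch than the chunked transformer), all <= 50.
DESK_EPOCH_CAPS = {
    "DAE": 35,
    "CAE": 1,
    "UNET": 1,
    "UNET_CHUNKS": 1,
    "TCN": 1,
    "TRANSFORMER": 45,
}

DESK_INPUT_LEN = 4_600
DESK_LIBRARY_SIZE = 10


def desk_scale_protocol(seed: int = 0) -> Protocol:
    """Reduced replication protocol: 10 metabolites, 4,600-point axis,
    1,500/300/50 train/val/test pairs, shrunken architectures
    (DAE 4600-460-46, transformer 2 layers / embedding 128 / 4 heads with
    46 x 100 chunking, CAE/UNet/TCN channel counts as in the full protocol),
    per-architecture epoch caps as in :data:`DESK_EPOCH_CAPS`."""
    library = builtin_library(DESK_LIBRARY_SIZE)
    aug = AugmentationConfig()
    corpus = CorpusConfig(
        n_all_present=900, n_with_dropout=900, train_count=1_500, val_count=300,
        test_count=50, seed=seed, n_points=DESK_INPUT_LEN,
    )
    quant_corpus = CorpusConfig(
        n_all_present=500, n_with_dropout=500, train_count=800, val_count=200,
        test_count=4, seed=seed + 1, n_points=DESK_INPUT_LEN,
    )
    specs = _conversion_specs(
        DESK_INPUT_LEN, dae=(460, 46),
        transformer=dict(d_model=128, n_layers=2, heads=4, ff=512),
        seed=seed,
    )
    train_cfgs = {
        name: TrainConfig(max_epochs=DESK_EPOCH_CAPS[name], patience=8,
                          batch_size=16, seed=seed)
        for name in CONVERSION_ARCHS
    }
    return Protocol(
        name="desk_scale",
        library=library,
        aug=aug,
        corpus=corpus,
        quant_aug=replace(aug, include_triplets=False),
        quant_corpus=quant_corpus,
        conversion_specs=specs,
        train_cfgs=train_cfgs,
        mlp_spec=QuantMLPSpec(DESK_INPUT_LEN, 100, DESK_LIBRARY_SIZE, seed=seed),
        mlp_train_cfg=TrainConfig(max_epochs=40, patience=8, batch_size=16,
                                  seed=seed, task="quantification"),
        desk_scale=True,
    )


def smoke_protocol(seed: int = 0) -> Protocol:
    """Minimal end-to-end protocol (toy library, 200 spectra, tiny
    transformer, 5 epochs) for fast pipeline checks."""
    library = builtin_library(3)
    aug = AugmentationConfig()
    corpus = CorpusConfig(
        n_all_present=100, n_with_dropout=100, train_count=160, val_count=40,
        test_count=4, seed=seed, n_points=460,
    )
    train = TrainConfig(max_epochs=5, patience=3, batch_size=16, seed=seed)
    specs = _conversion_specs(
        460, dae=(64, 16),
        transformer=dict(d_model=32, n_layers=1, heads=2, ff=64),
        seed=seed,
    )
    return Protocol(
        name="smoke",
        library=library,
        aug=aug,
        corpus=corpus,
        quant_aug=replace(aug, include_triplets=False),
        quant_corpus=replace(corpus, seed=seed + 1),
        conversion_specs=specs,
        train_cfgs={a: train for a in CONVERSION_ARCHS},
        mlp_spec=QuantMLPSpec(460, 16, 3, seed=seed),
        mlp_train_cfg=replace(train, task="quantification"),
        desk_scale=True,
    )


PRESETS = {
    "base": lambda seed: full_scale_protocol("base", seed),
    "adjusted_snr": lambda seed: full_scale_protocol("adjusted_snr", seed),
    "met87": lambda seed: full_scale_protocol("met87", seed),
    "desk_scale": desk_scale_protocol,
    "smoke": smoke_protocol,
}


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("out_dir", "seed")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValidationError("config must be a mapping or a YAML file path")
    return dict(config)


def _validate_config(cfg: dict) -> None:
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    bad = []
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        bad.append("seed (must be an integer)")
    preset = cfg.get("preset", "desk_scale")
    if preset not in PRESETS:
        bad.append(f"preset (unknown {preset!r}; known: {sorted(PRESETS)})")
    problems = [f"missing key {k!r}" for k in missing] + [f"invalid {b}" for b in bad]
    if problems:
        raise ValidationError("config validation failed: " + "; ".join(problems))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_experiment(config) -> Path:
    """Execute the requested stages of one experiment.

    ``config`` is a mapping (or YAML path) with keys: ``out_dir``; ``seed``;
    optional ``preset`` (default ``desk_scale``); optional ``stages``
    (subset of generate/train/evaluate, default all); optional
    ``architectures`` (subset of the conversion architectures); optional
    ``quantification`` flag (default True).  Generation is idempotent: an
    existing corpus whose stored manifest matches the requested config and
    seed is reused without recomputation.  Returns the artifact directory.
    """
    cfg = _load_config(config)
    _validate_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    preset = cfg.get("preset", "desk_scale")
    stages = list(cfg.get("stages", ["generate", "train", "evaluate"]))
    proto = PRESETS[preset](seed)
    if "architectures" in cfg:
        unknown = set(cfg["architectures"]) - set(proto.conversion_specs)
        if unknown:
            raise ValidationError(f"unknown architectures: {sorted(unknown)}")
        proto.conversion_specs = {
            k: v for k, v in proto.conversion_specs.items()
            if k in cfg["architectures"]
        }
    do_quant = bool(cfg.get("quantification", True))

    log_path = out_dir / "run.log"
    manifest = RunManifest(
        package_version=__version__,
        preset=preset,
        config_hash=_config_hash(cfg),
        seed=seed,
        architecture_specs={k: json.loads(spec_to_json(s))
                            for k, s in proto.conversion_specs.items()},
    )

    def log(msg: str) -> None:
        stamp = f"{time.monotonic():12.2f}s"
        with open(log_path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")

    corpus_path = out_dir / "corpus.h5"
    quant_path = out_dir / "quant_corpus.h5"
    if "generate" in stages:
        t0 = time.monotonic()
        if _corpus_is_current(corpus_path, proto.aug, proto.corpus):
            log(f"generate: reusing existing corpus {corpus_path.name}")
        else:
            build_corpus(proto.library, proto.aug, proto.corpus, corpus_path)
            log(f"generate: corpus in {time.monotonic() - t0:.1f}s")
        if do_quant:
            if _corpus_is_current(quant_path, proto.quant_aug, proto.quant_corpus):
                log(f"generate: reusing existing corpus {quant_path.name}")
            else:
                build_corpus(proto.library, proto.quant_aug, proto.quant_corpus,
                             quant_path)
                log("generate: quantification corpus done")
    manifest.corpus_hash = _file_hash(corpus_path) if corpus_path.exists() else ""
    manifest.quant_corpus_hash = _file_hash(quant_path) if quant_path.exists() else ""

    suite = None
    if "train" in stages or "evaluate" in stages:
        t0 = time.monotonic()
        corpus = load_corpus(corpus_path)
        suite = run_comparison_suite(
            corpus, proto.conversion_specs, proto.train_cfgs,
            out_dir / "conversion", corpus_id=proto.name,
        )
        log(f"train/evaluate conversion: {time.monotonic() - t0:.1f}s; "
            f"mean MSE: { {k: round(r.mean_mse, 8) for k, r in suite['reports'].items()} }")
        if do_quant:
            t0 = time.monotonic()
            quant_corpus = load_corpus(quant_path)
            levels = list(QUANT_LEVELS)
            level_samples = build_fixed_concentration_tests(
                proto.library, proto.quant_aug, levels, proto.quant_corpus,
                rng=np.random.default_rng(proto.quant_corpus.seed + 10_000),
            )
            converter = suite["models"].get("TRANSFORMER") if suite else None
            run_quantification_suite(
                quant_corpus, proto.mlp_spec, proto.mlp_train_cfg,
                level_samples, levels, converter, out_dir / "quantification",
                scale=suite["scale"] if converter is not None else None,
            )
            log(f"train/evaluate quantification: {time.monotonic() - t0:.1f}s")

    manifest.timestamps["completed_monotonic_s"] = round(time.monotonic(), 2)
    manifest.write(out_dir)
    return out_dir


def run_desk_scale_replication(seed: int, out_dir: str | Path,
                               work_dir: str | Path | None = None) -> dict:
    """Run the full desk-scale replication and return its measured numbers.

    Generates the conversion and quantification corpora, trains all six
    conversion architectures and the two quantification MLPs, and evaluates
    conversion test MSE per architecture plus MAPE per pipeline at the
    fixed 5/25/50 mM levels (both with the standard single noise draw and
    on noiseless variants).  Returns a dict with keys ``conversion``
    (architecture -> mean test MSE, on the shared normalized scale),
    ``mape`` (level -> pipeline -> percent), ``mape_noiseless``,
    ``n_test``, ``n_metabolites``, and the trained model handles.
    """
    from dataclasses import replace as _replace

    from .evaluation import quant_mape
    from .training import predict

    out_dir = Path(out_dir)
    work_dir = Path(work_dir) if work_dir else out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    work_dir.mkdir(parents=True, exist_ok=True)
    proto = desk_scale_protocol(seed)

    corpus_path = work_dir / "corpus.h5"
    build_corpus(proto.library, proto.aug, proto.corpus, corpus_path)
    corpus = load_corpus(corpus_path)
    suite = run_comparison_suite(
        corpus, proto.conversion_specs, proto.train_cfgs,
        out_dir / "conversion", corpus_id=proto.name,
    )

    quant_path = work_dir / "quant_corpus.h5"
    build_corpus(proto.library, proto.quant_aug, proto.quant_corpus, quant_path)
    quant_corpus = load_corpus(quant_path)
    levels = list(QUANT_LEVELS)
    level_samples = build_fixed_concentration_tests(
        proto.library, proto.quant_aug, levels, proto.quant_corpus,
        rng=np.random.default_rng(proto.quant_corpus.seed + 10_000),
    )
    quant = run_quantification_suite(
        quant_corpus, proto.mlp_spec, proto.mlp_train_cfg, level_samples,
        levels, suite["models"]["TRANSFORMER"], out_dir / "quantification",
        scale=suite["scale"],
    )

    noiseless = build_fixed_concentration_tests(
        proto.library, _replace(proto.quant_aug, noise_pp_frac=0.0), levels,
        proto.quant_corpus,
    )
    scale = quant["scale"]
    mape_noiseless: dict[float, dict[str, float]] = {}
    for level, sample in zip(levels, noiseless):
        mape_noiseless[level] = {
            side + "_direct": quant_mape(
                np.maximum(predict(quant["mlps"][side],
                                   getattr(sample, side).intensities / scale), 0.0),
                sample.conc,
            )
            for side in ("lf", "hf")
        }

    return {
        "protocol": proto,
        "conversion": {k: r.mean_mse for k, r in suite["reports"].items()},
        "reports": suite["reports"],
        "models": suite["models"],
        "histories": suite["histories"],
        "scale": suite["scale"],
        "mape": quant["report"].per_level_mape,
        "mape_noiseless": mape_noiseless,
        "mlps": quant["mlps"],
        "levels": levels,
        "n_test": proto.corpus.test_count,
        "n_metabolites": len(proto.library),
        "out_dir": out_dir,
        "corpus_path": corpus_path,
    }


def _corpus_is_current(path: Path, aug: AugmentationConfig,
                       corpus: CorpusConfig) -> bool:
    if not path.exists():
        return False
    try:
        stored = load_corpus(path)["manifest"]
    except Exception:
        return False
    return (stored.get("augmentation") == asdict(aug)
            and stored.get("corpus") == asdict(corpus))
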
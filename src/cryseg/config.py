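"""Run configuration: one flat set of validated keys shared by all stages."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # pre-processing
    preemphasis_alpha: float = 0.97
    frame_len_ms: float = 30.0
    overlap_ms: float = 21.0
    # cepstra
    n_filters: int = 26
    n_cepstra: int = 12
    delta_window: int = 2
    # pitch
    f0_min_hz: float = 75.0
    f0_max_hz: float = 1000.0
    voicing_threshold: float = 0.45
    # empirical mode decomposition
    sd_threshold: float = 0.2
    max_sifts: int = 100
    imf_indices: tuple[int, ...] = (3, 4, 5)
    # classifier
    model_kind: str = "gmm"            # "gmm" | "hmm"
    recipe: str = "fft-mfcc"           # "fft-mfcc" | "emd-mfcc"
    n_components: int = 40             # GMM mixtures (per class)
    n_states: int = 4                  # HMM emitting states
    n_mix: int = 10                    # mixtures per HMM state
    smooth_window: int = 1
    switch_penalty: float = 0.0
    # post-processing
    silence_span_ms: float = 250.0
    exp_band: tuple[float, float] = (250.0, 1000.0)
    ins_band: tuple[float, float] = (100.0, 800.0)
    linear_energy: bool = True
    # evaluation
    kfold: int = 10
    kfold_repeats: int = 1
    seed: int = 0
    provenance: str = field(default="defaults", compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.preemphasis_alpha < 1.0:
            raise ValueError("preemphasis_alpha must be in [0, 1)")
        if not 0 <= self.overlap_ms < self.frame_len_ms:
            raise ValueError("need 0 <= overlap_ms < frame_len_ms")
        if self.n_cepstra > self.n_filters:
            raise ValueError("n_cepstra must not exceed n_filters")
        if not 0 < self.f0_min_hz < self.f0_max_hz:
            raise ValueError("need 0 < f0_min_hz < f0_max_hz")
        if self.model_kind not in ("gmm", "hmm"):
            raise ValueError("model_kind must be 'gmm' or 'hmm'")
        if self.recipe not in ("fft-mfcc", "emd-mfcc"):
            raise ValueError("recipe must be 'fft-mfcc' or 'emd-mfcc'")
        if min(self.imf_indices) < 1:
            raise ValueError("imf_indices are 1-based")

    @property
    def frame_len_s(self) -> float:
        return self.frame_len_ms / 1000.0

    @property
    def overlap_s(self) -> float:
        return self.overlap_ms / 1000.0

    @property
    def hop_s(self) -> float:
        return (self.frame_len_ms - self.overlap_ms) / 1000.0

    def digest(self) -> str:
        """Short hash of the configuration, for reproducibility logging."""
        d = asdict(self)
        d.pop("provenance", None)
        return hashlib.sha256(repr(sorted(d.items())).encode()).hexdigest()[:10]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    values: dict = {}
    provenance = "defaults"
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values.update(loaded)
        provenance = str(path)
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("imf_indices", "exp_band", "ins_band"):
        if key in values and isinstance(values[key], list):
            values[key] = tuple(values[key])
    if overrides:
        provenance += " + overrides"
    return RunConfig(provenance=provenance, **values)
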
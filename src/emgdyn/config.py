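"""Single-file YAML run configuration.

One config governs a whole reproducible run: protocol, window geometry,
feature settings, classifier grid, gate constraints, evaluation options
and the master seed.  Every field has a default, and the effective
(fully resolved) config is snapshotted into the run directory, so there
are no hidden defaults outside the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .classification import ClassifierSpec
from .pipeline import SECTIONS
from .protocol import ProtocolSpec
from .windowing import WindowSpec


@dataclass
class RunConfig:
    protocol: dict = field(default_factory=dict)
    window: dict = field(default_factory=dict)
    n_subjects: int = 8
    master_seed: int = 0
    feature_sets: list[str] = field(default_factory=lambda: ["td_ar", "wt"])
    classifiers: list[str] = field(default_factory=lambda: ["lda", "svm_ovo", "svm_ovr"])
    sections: list[str] = field(default_factory=lambda: list(SECTIONS))
    svm_hyperparams: list | str = field(default_factory=lambda: [10.0, "scale"])
    vote_depth: int = 6
    train_decimation: int | None = None
    gate: dict = field(default_factory=lambda: {"overall_min": 0.97, "per_class_min": 0.85})

    def protocol_spec(self) -> ProtocolSpec:
        return ProtocolSpec(**self.protocol)

    def window_spec(self) -> WindowSpec:
        fs = self.protocol.get("fs", ProtocolSpec().fs)
        return WindowSpec(fs=fs, **self.window)

    def classifier_spec(self, kind: str) -> ClassifierSpec:
        hp = self.svm_hyperparams
        if isinstance(hp, list):
            hp = tuple(hp)
        return ClassifierSpec(kind=kind, hyperparams=hp, seed=self.master_seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
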
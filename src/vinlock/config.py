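"""Configuration: domain partitions and per-variant generator parameters.

Both live in editable YAML.  The packaged defaults describe the four vinculin
forms studied here (wild type, metavinculin, T12, T12-A974K); users point the
loaders at their own files to analyse other constructs or numbering schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

VARIANT_NAMES = ("vinculin", "metavinculin", "t12", "t12_a974k")


def _packaged(relpath: str):
    return resources.files("vinlock").joinpath("data", *relpath.split("/"))


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


class DomainPartition:
    """Mapping of domain label -> inclusive residue-number ranges.

    Labels follow the vinculin architecture: four head helix bundles D1-D4
    (their union is the head, Vh), the flexible hinge, the tail Vt and the
    metavinculin-specific insert.  Ranges must not overlap except for the
    insert, which by construction sits inside hinge/tail numbering space.
    """

    def __init__(self, domains: dict[str, list], tail_offset: int = 68):
        self.domains = {
            label: [tuple(int(x) for x in rng) for rng in ranges]
            for label, ranges in domains.items()
        }
        self.tail_offset = int(tail_offset)
        self._validate()

    def _validate(self) -> None:
        for label, ranges in self.domains.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"invalid range {lo}-{hi} for domain {label!r}")
        core = [l for l in self.domains if l != "insert"]
        spans = sorted(
            (lo, hi, l) for l in core for lo, hi in self.domains[l]
        )
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"overlapping ranges: {l1} {lo1}-{hi1} and {l2} {lo2}-{hi2}"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.domains)

    def contains(self, label: str, residue_number: int) -> bool:
        if label not in self.domains:
            raise KeyError(f"unknown domain label {label!r}")
        return any(lo <= residue_number <= hi for lo, hi in self.domains[label])

    def ranges(self, label: str) -> list[tuple[int, int]]:
        if label not in self.domains:
            raise KeyError(f"unknown domain label {label!r}")
        return self.domains[label]

    @classmethod
    def from_yaml(cls, path) -> "DomainPartition":
        raw = load_yaml(path)
        return cls(raw["domains"], raw.get("metavinculin_tail_offset", 68))

    @classmethod
    def default(cls) -> "DomainPartition":
        return cls.from_yaml(_packaged("partition.yaml"))


@dataclass
class StateParams:
    centroid: float  # A^2
    width: float     # A^2 (gaussian sd)


@dataclass
class TransitionParams:
    midpoint_v: float   # logistic midpoint, V
    sharpness_v: float  # logistic width, V (small = abrupt)


@dataclass
class VariantParams:
    """Generator ground truth for one vinculin form.

    The printed quantities (state centroids, transition placements, charge
    envelope breadth, extended fraction, decay slope) are transcribed in the
    packaged YAML files; everything else is a documented free choice.
    """

    name: str
    mass_da: float
    charge_weights: dict[int, float]
    peak_width_mz: float
    ciu_charge: int
    state_ccs: dict[str, StateParams]
    transitions: dict[str, TransitionParams]
    extended_fraction: float
    extended_ccs_min: float
    extended_ccs_max: float
    fa_lognormal: tuple[float, float]       # (mu, sigma) of log-area, um^2
    decay_rate_per_min: float
    decay_plateau: float
    bleach_rate_per_min: float
    seed: int
    compact_charge_range: tuple[int, int] = (19, 24)
    extended_charge_range: tuple[int, int] = (25, 56)

    def __post_init__(self):
        cents = [self.state_ccs[k].centroid for k in ("C", "SO", "O") if k in self.state_ccs]
        if cents != sorted(cents):
            raise ValueError("state centroids must be ordered C < SO < O")
        if not 0.0 <= self.extended_fraction <= 1.0:
            raise ValueError("extended_fraction must be in [0, 1]")
        for key, tr in self.transitions.items():
            if not 50.0 <= tr.midpoint_v <= 240.0:
                raise ValueError(f"transition {key} midpoint outside the 50-240 V grid")

    @classmethod
    def from_dict(cls, raw: dict) -> "VariantParams":
        return cls(
            name=raw["name"],
            mass_da=float(raw["mass_da"]),
            charge_weights={int(z): float(w) for z, w in raw["charge_weights"].items()},
            peak_width_mz=float(raw.get("peak_width_mz", 8.0)),
            ciu_charge=int(raw.get("ciu_charge", 17)),
            state_ccs={
                k: StateParams(float(v["centroid"]), float(v["width"]))
                for k, v in raw["state_ccs"].items()
            },
            transitions={
                k: TransitionParams(float(v["midpoint_v"]), float(v["sharpness_v"]))
                for k, v in raw["transitions"].items()
            },
            extended_fraction=float(raw.get("extended_fraction", 0.0)),
            extended_ccs_min=float(raw.get("extended_ccs_min", 7600.0)),
            extended_ccs_max=float(raw.get("extended_ccs_max", 13200.0)),
            fa_lognormal=(
                float(raw["fa_lognormal"]["mu"]),
                float(raw["fa_lognormal"]["sigma"]),
            ),
            decay_rate_per_min=float(raw["decay"]["rate_per_min"]),
            decay_plateau=float(raw["decay"]["plateau"]),
            bleach_rate_per_min=float(raw.get("bleach_rate_per_min", 0.005)),
            seed=int(raw.get("seed", 7)),
            compact_charge_range=tuple(raw.get("compact_charge_range", (19, 24))),
            extended_charge_range=tuple(raw.get("extended_charge_range", (25, 56))),
        )

    @classmethod
    def from_yaml(cls, path) -> "VariantParams":
        return cls.from_dict(load_yaml(path))


def load_variant(name_or_path: str | Path) -> VariantParams:
    """Load a packaged variant by name, or any parameter file by path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return VariantParams.from_yaml(p)
    name = str(name_or_path).lower().replace("-", "_")
    if name not in VARIANT_NAMES:
        raise KeyError(
            f"unknown variant {name_or_path!r}; packaged variants: {VARIANT_NAMES}"
        )
    return VariantParams.from_yaml(_packaged(f"variants/{name}.yaml"))
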
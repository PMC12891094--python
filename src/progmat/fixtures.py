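"""Randomized-but-valid item specifications for property testing, plus the
worked multi-layer logic example used throughout the documentation.

Every sampled spec satisfies the preconditions of the matrix builder by
construction (logical rules only on figures with at least three elements and
only in 3x3 matrices; the shape rule only on concatenations of exactly three
single figures; tag-gated rules only on figures carrying the tag).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator

from .errors import ConfigError
from .rules import LOGICAL_RULES, rule

__all__ = ["DEFAULT_RULES", "FixtureConfig", "sample_item_spec", "sample_item_specs", "tutorial_item"]

DEFAULT_RULES = (
    "identity", "size", "size.inv", "rotation", "rotation.inv", "lwd", "lwd.inv",
    "lty", "lty.inv", "shape", "shape.inv", "shade", "multi.shade",
    "AND", "OR", "XOR",
)

# starts compatible with any rule requirement they get paired with
_ROTATE_STARTS = ("square", "triangle", "pentagon", "hexagon", "ellipse", "square4", "cross")
_FILL_STARTS = ("square", "triangle", "pentagon", "hexagon", "circle", "ellipse", "malta", "eight")
_ANY_STARTS = _ROTATE_STARTS + _FILL_STARTS + ("miley", "vline", "hline", "semicircle")
_SHAPE_TRIPLES = (("hexagon", "pentagon", "square"), ("circle", "triangle", "ellipse"),
                  ("square", "circle", "hexagon"))
_LOGICAL_STARTS = ("square4", "miley", "malta")


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_items: int = 10
    allowed_rules: tuple = DEFAULT_RULES
    layer_range: tuple = (1, 2)
    mat_types: tuple = (4, 9)
    include_degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.layer_range
        if not (1 <= lo <= hi <= 4):
            raise ConfigError(f"layer_range must lie within [1, 4], got {self.layer_range}")
        if not self.allowed_rules:
            raise ConfigError("allowed_rules must be non-empty")
        for name in self.allowed_rules:
            rule(name)  # raises RegistryError / UnsupportedRuleError early
        if not set(self.mat_types) <= {4, 9}:
            raise ConfigError(f"mat_types must be a subset of {{4, 9}}, got {self.mat_types}")
        if not self.mat_types:
            raise ConfigError("mat_types must be non-empty")
        only_logical = all(n in LOGICAL_RULES for n in self.allowed_rules)
        if only_logical and 9 not in self.mat_types:
            raise ConfigError("logical rules require 9-cell matrices, but 9 is not allowed")


def _start_spec(rng: random.Random, rname: str) -> dict:
    """A start-figure spec satisfying the requirements of ``rname``."""
    base = rule(rname).base
    if base in LOGICAL_RULES:
        return {"primitive": rng.choice(_LOGICAL_STARTS)}
    if base == "shape":
        triple = rng.choice(_SHAPE_TRIPLES)
        return {"cof": [{"primitive": p} for p in triple]}
    if base == "rotation":
        return {"primitive": rng.choice(_ROTATE_STARTS)}
    if base in ("shade", "multi.shade"):
        return {"primitive": rng.choice(_FILL_STARTS)}
    return {"primitive": rng.choice(_ANY_STARTS)}


def _sample_layer(rng: random.Random, rules: list, mat_type: int) -> tuple[dict, list, list]:
    rname = rng.choice(rules)
    start = _start_spec(rng, rname)
    if rname in LOGICAL_RULES:
        direction = rng.choice(("h", "v"))
    else:
        direction = rng.choice(("h", "v", "both"))
    hrules = [rname] if direction in ("h", "both") else ["identity"]
    vrules = [rname] if direction in ("v", "both") else ["identity"]
    return start, hrules, vrules


def sample_item_spec(cfg: FixtureConfig, rng: random.Random, index: int = 0) -> dict:
    """Draw one valid item spec."""
    logical_ok = 9 in cfg.mat_types
    rules = [n for n in cfg.allowed_rules
             if logical_ok or n not in LOGICAL_RULES]
    lo, hi = cfg.layer_range
    n_layers = rng.randint(lo, hi)
    starts, hrules, vrules = [], [], []
    has_logical = False
    for li in range(n_layers):
        layer_rules = rules
        if has_logical:
            # one logical rule per item keeps directional logic well defined
            layer_rules = [n for n in rules if n not in LOGICAL_RULES] or ["identity"]
        s, h, v = _sample_layer(rng, layer_rules, 9)
        if any(n in LOGICAL_RULES for n in h + v):
            has_logical = True
        starts.append(s)
        hrules.append(h)
        vrules.append(v)
    mat_type = 9 if has_logical else rng.choice(cfg.mat_types)
    return {
        "start": starts,
        "hrules": hrules,
        "vrules": vrules,
        "mat_type": mat_type,
        "seed": rng.randint(0, 10_000),
        "id": f"item-{index:04d}",
    }


def _degenerate_specs() -> list[dict]:
    """Edge cases exercising every documented warning path."""
    return [
        # single layer -> IC-Inc fallback
        {"start": [{"primitive": "square"}], "hrules": [["size"]],
         "vrules": [["identity"]], "mat_type": 9, "seed": 1, "id": "degenerate-single-layer"},
        # vertical-only single rule -> r_left equals the correct response
        {"start": [{"primitive": "square"}], "hrules": [["identity"]],
         "vrules": [["shade"]], "mat_type": 9, "seed": 1, "id": "degenerate-vertical-only"},
        # no fill-capable layer anywhere (miley foreground) -> IC-Neg fallback
        {"start": [{"primitive": "square4"}, {"primitive": "miley"}],
         "hrules": [["rotation.4"], ["identity"]],
         "vrules": [["identity"], ["size"]],
         "mat_type": 9, "seed": 1, "id": "degenerate-no-fill"},
    ]


def sample_item_specs(cfg: FixtureConfig) -> Iterator[dict]:
    """Deterministic stream of ``cfg.n_items`` valid item specs.

    With ``include_degenerate`` the known-warning edge cases are appended.
    """
    rng = random.Random(f"fixtures:{cfg.seed}")
    for i in range(cfg.n_items):
        yield sample_item_spec(cfg, rng, i)
    if cfg.include_degenerate:
        yield from _degenerate_specs()


def tutorial_item(seed: int = 1) -> dict:
    """The worked example: AND on a four-line square (horizontal logic)
    layered under OR on a four-petal flower (vertical logic), 3x3."""
    return {
        "start": [{"primitive": "square4"}, {"primitive": "miley"}],
        "hrules": [["AND"], ["identity"]],
        "vrules": [["identity"], ["OR"]],
        "mat_type": 9,
        "seed": seed,
        "id": "tutorial",
    }
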
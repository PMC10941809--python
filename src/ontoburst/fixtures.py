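"""Seeded generators of synthetic ontologies and count annotations.

Everything here is deterministic given the seed, so transforms and
renderers can be tested (and benchmarked) without downloading any real
ontology release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .model import TermRecord

__all__ = ["FixtureSpec", "generate_forest_records", "make_mini_atc"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and count distribution of a synthetic GENERIC forest.

    Counts follow a zero-inflated rounded log-normal, echoing heavy-tailed
    annotation counts (trial or publication numbers).
    """

    n_roots: int = 3
    depth: int = 3
    branching: tuple[int, int] = (2, 3)
    zero_inflation: float = 0.3
    lognormal_mean: float = 1.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ConfigError("n_roots must be >= 1")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        lo, hi = self.branching
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad branching range {self.branching}")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigError("zero_inflation must be in [0, 1]")


def generate_forest_records(spec: FixtureSpec) -> list[TermRecord]:
    """Generate GENERIC-grammar records forming a complete forest.

    Codes are dot-joined zero-padded ordinals (``001``, ``001.002``, ...).
    Identical specs (including seed) yield identical record lists.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.branching
    records: list[TermRecord] = []

    def draw_count() -> float:
        if rng.random() < spec.zero_inflation:
            return 0.0
        return float(round(rng.lognormal(spec.lognormal_mean, spec.lognormal_sigma)))

    def grow(code: str, level: int) -> None:
        records.append(
            TermRecord(code=code, label=f"term {code}", count=draw_count())
        )
        if level >= spec.depth:
            return
        n_children = int(rng.integers(lo, hi + 1))
        for j in range(1, n_children + 1):
            grow(f"{code}.{j:03d}", level + 1)

    for i in range(1, spec.n_roots + 1):
        grow(f"{i:03d}", 1)
    return records


def make_mini_atc() -> list[TermRecord]:
    """Hand-written ~15-node ATC fixture used across unit tests.

    Contains one fully populated 5-level chain under "J" plus a designated
    zero-count decoy leaf (``J05AB09``) that drop-empty pruning removes.
    """
    return [
        TermRecord("J", "Anti-infectives for systemic use"),
        TermRecord("J01", "Antibacterials for systemic use"),
        TermRecord("J01C", "Beta-lactam antibacterials, penicillins"),
        TermRecord("J01CA", "Penicillins with extended spectrum"),
        TermRecord("J01CA04", "amoxicillin", count=6.0),
        TermRecord("J05", "Antivirals for systemic use"),
        TermRecord("J05A", "Direct acting antivirals"),
        TermRecord("J05AB", "Nucleosides and nucleotides"),
        TermRecord("J05AB01", "aciclovir", count=3.0),
        TermRecord("J05AB04", "ribavirin", count=5.0, description="broad-spectrum"),
        TermRecord("J05AB09", "famciclovir", count=0.0),  # decoy zero leaf
        TermRecord("N", "Nervous system"),
        TermRecord("N02", "Analgesics"),
        TermRecord("N02B", "Other analgesics and antipyretics"),
        TermRecord("N02BE", "Anilides"),
        TermRecord("N02BE01", "paracetamol", count=7.0, color="#00FF00"),
    ]
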
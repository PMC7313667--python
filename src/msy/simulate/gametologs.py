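"""Gametolog pairs evolved under a strict synonymous molecular clock.

X and Y copies descend from a common ancestral coding sequence and stop
exchanging material at the (true) split age; each lineage then
accumulates substitutions independently.  Mutations are restricted to
third codon positions, evolving as a Jukes-Cantor process at the
per-synonymous-site rate, with proposals creating stop codons rejected.

Root sequences are drawn from a 40-codon alphabet that excludes codons
whose first two bases are TA, TG, TT, CT, AG or CG.  This removes (a)
every codon one third-position change away from a stop, so rejection
never distorts the process, and (b) every codon with first-position
synonymous degeneracy (Leu/Arg), so all synonymous sites sit at third
positions.  Under that alphabet the NG86 + Jukes-Cantor estimator of dS
is exactly calibrated to the simulation at any divergence: expected dS
equals rate x time per lineage.

The default rate of 0.001 synonymous substitutions per site per Myr per
lineage is the canonical vertebrate neutral rate (~1e-9 / site / year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ..clock import CODONS, Calibration, _STOPS

__all__ = [
    "ClockSimSpec",
    "SAFE_CODONS",
    "random_cds",
    "evolve_codons",
    "simulate_gametolog_pair",
    "dated_topology",
    "expected_pairwise_ds",
]

_SAFE_PREFIXES = ("AA", "AC", "AT", "CA", "CC", "GA", "GC", "GG", "GT", "TC")
SAFE_CODONS = tuple(p + b for p in _SAFE_PREFIXES for b in "ACGT")
_STOP_IDX = np.array([CODONS.index(s) for s in sorted(_STOPS)])

DEFAULT_RATE = 0.001  # synonymous substitutions / synonymous site / Myr / lineage
DEFAULT_CALIBRATIONS = (("OutA", 184.9), ("OutB", 311.9))  # Myr to MRCA with X


@dataclass(frozen=True)
class ClockSimSpec:
    """Ground truth for one clock simulation.

    ``outgroup_ages`` lists outgroup taxa by the age (Myr) of their
    common ancestor with the X lineage, oldest being the root.  The true
    X/Y split age must be younger than every outgroup age.
    """

    true_age: float
    rate: float = DEFAULT_RATE
    outgroup_ages: tuple[tuple[str, float], ...] = DEFAULT_CALIBRATIONS
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if self.true_age < 0:
            raise ValueError("true_age must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.outgroup_ages:
            raise ValueError("at least one dated outgroup is required")
        ages = [a for _, a in self.outgroup_ages]
        if sorted(ages) != ages:
            raise ValueError("outgroup ages must be listed youngest to oldest")
        if self.true_age >= min(ages):
            raise ValueError("true_age must be younger than every outgroup split age")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def root_age(self) -> float:
        return self.outgroup_ages[-1][1]

    def calibrations(self, x: str = "X") -> list[Calibration]:
        return [(x, name, age) for name, age in self.outgroup_ages]


def random_cds(n_codons: int, gc_content: float, rng: np.random.Generator) -> np.ndarray:
    """Codon-index array sampled from the safe alphabet, GC-weighted."""
    w = np.array(
        [
            np.prod([gc_content / 2 if b in "GC" else (1 - gc_content) / 2 for b in codon])
            for codon in SAFE_CODONS
        ]
    )
    w /= w.sum()
    picks = rng.choice(len(SAFE_CODONS), size=n_codons, p=w)
    safe_idx = np.array([CODONS.index(c) for c in SAFE_CODONS])
    return safe_idx[picks]


def evolve_codons(
    codons: np.ndarray, time: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve third positions for ``time`` Myr under Jukes-Cantor at ``rate``.

    Each third position substitutes at total rate ``rate`` (per Myr);
    substitutions proposing a stop codon are rejected and redrawn among
    the remaining alternatives.
    """
    if time < 0:
        raise ValueError("time must be >= 0")
    out = codons.copy()
    p_same = 0.25 + 0.75 * np.exp(-4.0 * rate * time / 3.0)
    changed = np.flatnonzero(rng.random(len(out)) > p_same)
    if changed.size == 0:
        return out
    offsets = rng.integers(1, 4, size=changed.size)  # 1..3: which other base
    for i, off in zip(changed, offsets):
        base = out[i] % 4
        prefix = out[i] - base
        candidates = [prefix + b for b in range(4) if b != base]
        new = candidates[off - 1]
        if new in _STOP_IDX:
            allowed = [c for c in candidates if c not in _STOP_IDX]
            if not allowed:
                continue  # substitution rejected outright
            new = allowed[(off - 1) % len(allowed)]
        out[i] = new
    return out


def expected_pairwise_ds(age: float, rate: float) -> float:
    """Expected synonymous divergence between two lineages split ``age`` Myr ago."""
    return 2.0 * age * rate


def simulate_gametolog_pair(
    spec: ClockSimSpec,
    gene_length_codons: int,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """One gene's X/Y pair plus outgroup orthologs, as codon-index arrays.

    The lineage runs root -> (successively younger outgroup splits) ->
    X/Y split; each branch is evolved independently.  Warns when the
    deepest pairwise divergence approaches NG86 saturation (expected
    proportion of synonymous differences >= 95% of the 3/4 ceiling).
    """
    if gene_length_codons < 50:
        raise ValueError("gene_length_codons must be >= 50 for stable dS estimates")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    deepest = expected_pairwise_ds(spec.root_age, spec.rate)
    if 0.75 * (1.0 - np.exp(-4.0 * deepest / 3.0)) >= 0.95 * 0.75:
        warnings.warn(
            f"rate x age implies expected ps near the 3/4 NG86 ceiling "
            f"(deepest pairwise dS {deepest:.2f}); estimates will saturate"
        )
    seqs: dict[str, np.ndarray] = {}
    lineage = random_cds(gene_length_codons, spec.gc_content, rng)
    # walk from the oldest split to the youngest, peeling one outgroup at
    # each split and evolving the surviving lineage down to the next one
    splits = list(reversed(spec.outgroup_ages))
    for i, (name, age) in enumerate(splits):
        seqs[name] = evolve_codons(lineage, age, spec.rate, rng)
        next_age = splits[i + 1][1] if i + 1 < len(splits) else spec.true_age
        lineage = evolve_codons(lineage, age - next_age, spec.rate, rng)
    seqs["X"] = evolve_codons(lineage, spec.true_age, spec.rate, rng)
    seqs["Y"] = evolve_codons(lineage, spec.true_age, spec.rate, rng)
    return seqs


def dated_topology(spec: ClockSimSpec) -> dendropy.Tree:
    """Rooted topology (((X,Y),youngest outgroup)...,oldest outgroup)."""
    newick = "(X,Y)"
    for name, _age in spec.outgroup_ages:
        newick = f"({newick},{name})"
    return dendropy.Tree.get(data=newick + ";", schema="newick")
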
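"""Synthetic labeled protein families for end-to-end testing.

Each receptor-like class is defined by a distinct random residue motif
planted at a random position inside an otherwise random background
sequence; a motif-free background class plays the non-receptor role.
Motif residues are drawn from one shared, compositionally biased profile
(a Dirichlet draw over the 20 residues), emulating the atypical residue
usage of a conserved superfamily domain — real receptor DNA-binding
domains, for instance, are cysteine/arginine-rich zinc fingers.  The bias
displaces every receptor-like family off the center of the background
cloud, which is what makes the receptor/background decision learnable;
without it a motif-free query is equidistant in expectation from every
reference.  Per-residue mutation noise controls the within-class spread,
hence the between-class separation seen by the classifier.  Everything is
driven by one seed, so a spec reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .sequence_io import CANONICAL_RESIDUES, ProteinRecord

NONNR_LABEL = "NONNR"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic family collection.

    ``n_classes`` counts all classes including the motif-free background
    (so the default 8 means seven receptor-like families plus NONNR,
    mirroring the seven-subfamily problem).  Sequence lengths are drawn
    uniformly from ``length_range``; the minimum must be at least 21 so
    every sequence supports the Fourier block.  ``motif_concentration`` is
    the Dirichlet concentration of the shared motif residue profile:
    smaller values give a spikier, more atypical domain composition (1.0
    would make motifs compositionally indistinguishable from background on
    average).
    """

    n_classes: int = 8
    per_class: int = 20
    length_range: tuple[int, int] = (80, 120)
    motif_length: int = 40
    mutation_rate: float = 0.01
    seed: int = 0
    motif_concentration: float = 0.3

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.per_class < 2:
            raise ParameterError("per_class must be >= 2")
        lo, hi = self.length_range
        if lo < 21 or hi < lo:
            raise ParameterError("length_range must satisfy 21 <= min <= max")
        if not 0 <= self.mutation_rate < 1:
            raise ParameterError("mutation_rate must be in [0, 1)")
        if self.motif_length < 1 or self.motif_length > lo:
            raise ParameterError(
                f"motif_length {self.motif_length} must be in [1, min length {lo}]"
            )
        if self.motif_concentration <= 0:
            raise ParameterError("motif_concentration must be positive")


def _random_residues(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 20, size=n)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position with probability ``rate``, always to a
    different residue so the nominal rate is the realized rate."""
    if rate == 0:
        return seq
    hit = rng.random(seq.size) < rate
    if hit.any():
        seq = seq.copy()
        # shift by 1..19 mod 20 guarantees a change
        seq[hit] = (seq[hit] + rng.integers(1, 20, size=int(hit.sum()))) % 20
    return seq


def generate_fixture(spec: FixtureSpec) -> list[ProteinRecord]:
    """Generate labeled records: classes NR1..NR(k-1) plus NONNR."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    n_motif_classes = spec.n_classes - 1
    profile = rng.dirichlet(np.full(20, spec.motif_concentration))
    motifs = [
        rng.choice(20, size=spec.motif_length, p=profile)
        for _ in range(n_motif_classes)
    ]
    records: list[ProteinRecord] = []
    for ci in range(spec.n_classes):
        label = f"NR{ci + 1}" if ci < n_motif_classes else NONNR_LABEL
        for si in range(spec.per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = _random_residues(rng, L)
            if ci < n_motif_classes:
                pos = int(rng.integers(0, L - spec.motif_length + 1))
                seq[pos : pos + spec.motif_length] = motifs[ci]
            seq = _mutate(rng, seq, spec.mutation_rate)
            records.append(
                ProteinRecord(
                    identifier=f"SYN{spec.seed}_{label}_{si:04d}",
                    sequence="".join(CANONICAL_RESIDUES[i] for i in seq),
                    label=label,
                )
            )
    return records


def shuffle_labels(
    records: list[ProteinRecord], rng: np.random.Generator
) -> list[ProteinRecord]:
    """Randomly permute the labels across records (chance baseline)."""
    labels = [r.label for r in records]
    perm = rng.permutation(len(labels))
    return [replace(r, label=labels[p]) for r, p in zip(records, perm)]
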
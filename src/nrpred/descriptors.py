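"""Sequence-derived feature groups.

Four descriptor families are computed from a validated residue string:

* amino acid composition (AAC) — 20 normalized residue frequencies;
* gapped dipeptide composition DC(g) — 400 ordered-pair frequencies with
  ``g`` intervening positions (g = 0 is the classical dipeptide composition);
* Lempel-Ziv complexity factor (CF) — the number of components in the
  sequence's exhaustive synthesis history;
* Fourier spectrum components (FSC) — amplitudes and phases of the first 10
  non-constant DFT terms of a per-residue physicochemical property signal,
  for three property scales (hydrophobicity, hydrophilicity, side-chain
  mass), 60 values in total.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import DimensionError, InputError, TooShortError
from .sequence_io import CANONICAL_RESIDUES

AA_ORDER = CANONICAL_RESIDUES
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Fixed order of the three property scales in the Fourier block.
SCALE_ORDER = ("hydrophobicity", "hydrophilicity", "side_chain_mass")

#: Number of low-frequency DFT components retained per scale.
N_FOURIER_COMPONENTS = 10

#: Amplitudes below this are treated as zero and get phase 0 (arg() is
#: numerically meaningless at the origin).
_AMPLITUDE_EPS = 1e-12


def _encode(sequence: str) -> np.ndarray:
    if not sequence:
        raise InputError("empty sequence")
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise InputError(f"non-canonical residue {exc.args[0]!r}; validate first")


def aac(sequence: str) -> np.ndarray:
    """Amino acid composition: 20 normalized residue frequencies.

    Component ``u`` is (count of residue u) / L in alphabetical residue
    order; the components sum to 1.
    """
    idx = _encode(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(idx)


def gapped_dipeptide(sequence: str, g: int) -> np.ndarray:
    """Gapped dipeptide composition DC(g): 400 ordered-pair frequencies.

    Component (a, b), in first-residue-major alphabetical order, counts
    positions i with R(i) = a and R(i+g+1) = b, divided by L - 1 - g (the
    number of g-gapped pairs) so the vector sums to 1.
    """
    if g < 0:
        raise InputError(f"gap must be non-negative, got {g}")
    idx = _encode(sequence)
    L = len(idx)
    if L < g + 2:
        raise TooShortError(f"length {L} < {g + 2} required for DC(g={g})")
    first = idx[: L - 1 - g]
    second = idx[g + 1 :]
    pair = first * 20 + second
    counts = np.bincount(pair, minlength=400).astype(float)
    return counts / (L - 1 - g)


@dataclass(frozen=True)
class LzSynthesis:
    """Exhaustive-history decomposition of a sequence.

    ``components`` concatenate to the input exactly; ``complexity`` is the
    number of components (the minimal number of synthesis steps, each step
    either inserting a new symbol or copying the longest reproducible
    fragment).
    """

    components: tuple[str, ...]
    complexity: int


def lz_complexity(sequence: str) -> LzSynthesis:
    """Lempel-Ziv complexity of a residue string via the exhaustive history.

    Scanning left to right, the current component Q is extended one symbol
    at a time while Q occurs as a substring of the already-synthesized
    prefix concatenated with Q minus its last character; when the extension
    is no longer reproducible the component is closed and a new one starts.
    """
    if not sequence:
        raise InputError("empty sequence")
    n = len(sequence)
    components: list[str] = []
    i = 0
    while i < n:
        k = 1
        # grow Q = sequence[i:i+k] while reproducible from the prefix
        # extended by Q minus its last character
        while i + k <= n and sequence[i : i + k] in sequence[: i + k - 1]:
            k += 1
        components.append(sequence[i : min(i + k, n)])
        i += k
    return LzSynthesis(tuple(components), len(components))


@dataclass(frozen=True)
class PropertyScale:
    """One physicochemical property scale over the 20 canonical residues.

    ``standardized_values`` are the raw values shifted and scaled to zero
    mean and unit (population) standard deviation over the 20 residues, so
    the three scales become commensurable before signal construction.
    """

    name: str
    raw_values: Mapping[str, float]
    standardized_values: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(AA_ORDER) - set(self.raw_values)
        extra = set(self.raw_values) - set(AA_ORDER)
        if missing or extra:
            raise InputError(
                f"scale {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        vals = np.array([self.raw_values[a] for a in AA_ORDER], dtype=float)
        std = (vals - vals.mean()) / vals.std()
        object.__setattr__(
            self, "standardized_values", dict(zip(AA_ORDER, std.tolist()))
        )


def load_property_scales(path=None) -> tuple[PropertyScale, ...]:
    """Load the three property scales, in fixed order, from a TSV table.

    The packaged table ships the standard pseudo-amino-acid-composition
    hydrophobicity, hydrophilicity and side-chain-mass values; an alternative
    table with the same three named columns may be supplied.
    """
    if path is None:
        source = importlib.resources.files("nrpred.data") / "property_scales.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    try:
        cols = {name: header.index(name) for name in ("residue", *SCALE_ORDER)}
    except ValueError as exc:
        raise InputError(f"property table missing column: {exc}") from exc
    raw: dict[str, dict[str, float]] = {name: {} for name in SCALE_ORDER}
    for line in lines[1:]:
        parts = line.split("\t")
        residue = parts[cols["residue"]]
        for name in SCALE_ORDER:
            raw[name][residue] = float(parts[cols[name]])
    return tuple(PropertyScale(name, raw[name]) for name in SCALE_ORDER)


def property_signal(sequence: str, scale: PropertyScale) -> np.ndarray:
    """Convert a sequence to a digit signal of standardized property values."""
    if not sequence:
        raise InputError("empty sequence")
    return np.array([scale.standardized_values[c] for c in sequence], dtype=float)


@dataclass(frozen=True)
class SpectrumBlock:
    """Low-frequency DFT summary of one property signal."""

    amplitudes: np.ndarray
    phases: np.ndarray
    scale_name: str


def dft_low_frequency(
    signal: Sequence[float],
    n_components: int = N_FOURIER_COMPONENTS,
    scale_name: str = "",
) -> SpectrumBlock:
    """Amplitudes and phases of DFT terms k = 1..n_components.

    X(k) = sum_n x(n) exp(-2*pi*i*k*n/L).  The constant k = 0 term is
    excluded: its phase is identically 0 for a real signal and its amplitude
    duplicates composition information.  Requires L >= 2*n_components + 1 so
    the retained terms sit below the conjugate-symmetry fold-over.
    """
    x = np.asarray(signal, dtype=float)
    L = x.size
    if L < 2 * n_components + 1:
        raise TooShortError(
            f"signal length {L} < {2 * n_components + 1} required for "
            f"{n_components} Fourier components"
        )
    spectrum = np.fft.fft(x)[1 : n_components + 1]
    amplitudes = np.abs(spectrum)
    phases = np.angle(spectrum)
    phases = np.where(amplitudes < _AMPLITUDE_EPS, 0.0, phases)
    return SpectrumBlock(amplitudes, phases, scale_name)


def fourier_features(
    sequence: str, scales: Optional[Sequence[PropertyScale]] = None
) -> np.ndarray:
    """The 60 Fourier spectrum components of a sequence.

    For each scale in fixed order (hydrophobicity, hydrophilicity,
    side-chain mass): 10 amplitudes then 10 phases.
    """
    if scales is None:
        scales = load_property_scales()
    if len(scales) != 3:
        raise DimensionError(f"expected 3 property scales, got {len(scales)}")
    parts = []
    for scale in scales:
        block = dft_low_frequency(
            property_signal(sequence, scale), scale_name=scale.name
        )
        parts.append(block.amplitudes)
        parts.append(block.phases)
    return np.concatenate(parts)
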
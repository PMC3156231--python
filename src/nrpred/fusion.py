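"""Assembly of the four descriptor groups into the 881-D feature vector.

The pseudo amino acid composition used here is a weighted concatenation:
the 20 AAC frequencies unweighted, the two 400-component gapped dipeptide
blocks scaled by ``w_dc``, the scalar complexity factor by ``w_cf`` and the
60 Fourier spectrum components by ``w_fsc``.  All relative scaling between
descriptor families lives in these weights; the classifier applies none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import descriptors
from .descriptors import PropertyScale
from .errors import DimensionError, ParameterError
from .sequence_io import ProteinRecord

#: Total feature dimensionality and the named block layout.
N_FEATURES = 881
BLOCKS = {
    "AAC": slice(0, 20),
    "DC0": slice(20, 420),
    "DC1": slice(420, 820),
    "CF": slice(820, 821),
    "FSC": slice(821, 881),
}

#: Feature subsets used in the ablation study.
ABLATION_MODES = {
    "AAC": ("AAC",),
    "AAC+DC(0)": ("AAC", "DC0"),
    "AAC+DC(1)": ("AAC", "DC1"),
    "AAC+CF": ("AAC", "CF"),
    "AAC+FSC": ("AAC", "FSC"),
    "ALL": ("AAC", "DC0", "DC1", "CF", "FSC"),
}


@dataclass(frozen=True)
class FusionWeights:
    """Weight factors applied to the descriptor blocks at fusion time.

    The dipeptide weight of 20 makes the two DC blocks the dominant term of
    the Euclidean metric, as intended by the feature design.  The complexity
    factor grows like L/log L and the DFT amplitudes like sqrt(L), so their
    defaults scale them down to the composition blocks' per-component
    magnitude; both are configuration parameters.
    """

    w_dc: float = 20.0
    w_cf: float = 0.001
    w_fsc: float = 0.01

    def __post_init__(self) -> None:
        for name in ("w_dc", "w_cf", "w_fsc"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class PseaacVector:
    """881 ordered real components with the AAC/DC0/DC1/CF/FSC block layout."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_FEATURES,):
            raise DimensionError(
                f"feature vector must have {N_FEATURES} components, "
                f"got shape {arr.shape}"
            )
        object.__setattr__(self, "values", arr)

    def block(self, name: str) -> np.ndarray:
        return self.values[BLOCKS[name]]


def _check_block(arr, name: str, size: int) -> np.ndarray:
    out = np.asarray(arr, dtype=float).ravel()
    if out.size != size:
        raise DimensionError(f"block {name} must have {size} components, got {out.size}")
    return out


def fuse(aac, dc0, dc1, cf, fsc, weights: FusionWeights = FusionWeights()) -> PseaacVector:
    """Concatenate the descriptor blocks under the fusion weights."""
    aac = _check_block(aac, "AAC", 20)
    dc0 = _check_block(dc0, "DC0", 400)
    dc1 = _check_block(dc1, "DC1", 400)
    cf = _check_block(cf, "CF", 1)
    fsc = _check_block(fsc, "FSC", 60)
    return PseaacVector(
        np.concatenate(
            [
                aac,
                weights.w_dc * dc0,
                weights.w_dc * dc1,
                weights.w_cf * cf,
                weights.w_fsc * fsc,
            ]
        )
    )


def featurize(
    record: ProteinRecord,
    weights: FusionWeights = FusionWeights(),
    scales: Optional[Sequence[PropertyScale]] = None,
) -> PseaacVector:
    """Compute all descriptor groups for a validated record and fuse them."""
    if scales is None:
        scales = descriptors.load_property_scales()
    seq = record.sequence
    return fuse(
        descriptors.aac(seq),
        descriptors.gapped_dipeptide(seq, 0),
        descriptors.gapped_dipeptide(seq, 1),
        [float(descriptors.lz_complexity(seq).complexity)],
        descriptors.fourier_features(seq, scales),
        weights,
    )


def featurize_records(
    records: Sequence[ProteinRecord],
    weights: FusionWeights = FusionWeights(),
    scales: Optional[Sequence[PropertyScale]] = None,
) -> np.ndarray:
    """Feature matrix (n_records x 881) for a batch of validated records."""
    if scales is None:
        scales = descriptors.load_property_scales()
    return np.vstack([featurize(r, weights, scales).values for r in records])


def mode_columns(mode: str) -> np.ndarray:
    """Column indices of an ablation feature mode within the 881-D layout."""
    if mode not in ABLATION_MODES:
        raise ParameterError(
            f"unknown feature mode {mode!r}; valid: {sorted(ABLATION_MODES)}"
        )
    return np.concatenate(
        [np.arange(N_FEATURES)[BLOCKS[b]] for b in ABLATION_MODES[mode]]
    )


def write_feature_matrix(records, matrix: np.ndarray, path) -> None:
    """Export a feature matrix as TSV with block-encoded column names."""
    names = []
    for block, sl in BLOCKS.items():
        names.extend(f"{block}_{i}" for i in range(sl.stop - sl.start))
    with open(path, "w") as handle:
        handle.write("identifier\t" + "\t".join(names) + "\n")
        for rec, row in zip(records, matrix):
            handle.write(
                rec.identifier + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n"
            )
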
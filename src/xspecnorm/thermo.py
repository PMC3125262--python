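"""Nearest-neighbor duplex free energy at 37 °C.

Computes the Gibbs free energy of duplex formation, ΔG37, for a probe
hybridized to its exact complement, under the nearest-neighbor model with
the unified 1 M NaCl parameter set (16 Watson–Crick stacking terms, a
duplex-initiation term, and a per-end terminal A·T penalty).  ΔG37 is the
covariate of the control-probe regression in :mod:`xspecnorm.normalize`:
more negative values mean stronger (non-specific) binding.

No salt or temperature correction is applied: ΔG37 enters the analysis
only as a regression covariate, so any affine rescaling of the parameter
table is absorbed by the fitted slope and intercept.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NNParameterTable",
    "delta_g37",
    "delta_g37_many",
    "reverse_complement",
    "load_parameter_table",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STEPS = tuple(a + b for a in _BASES for b in _BASES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an unambiguous DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor ΔG37 parameters (kcal/mol).

    Parameters
    ----------
    stack_dg37
        Stacking free energy for each of the 16 dinucleotide steps,
        keyed by the top-strand step read 5'→3' (e.g. ``"AC"``).
    init_dg37
        Duplex initiation term, counted once per duplex.  The shipped
        unified table uses 1.96 kcal/mol (two G·C-terminated ends at
        0.98 each); A·T-terminated ends pay ``terminal_at_penalty`` extra.
    terminal_at_penalty
        Penalty added once per duplex end whose terminal base pair is A·T.
    """

    stack_dg37: Mapping[str, float]
    init_dg37: float
    terminal_at_penalty: float
    _lut: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [s for s in _STEPS if s not in self.stack_dg37]
        if missing:
            raise ValueError(f"parameter table missing stacks: {missing}")
        vals = np.array([self.stack_dg37[s] for s in _STEPS], dtype=float)
        if not np.all(np.isfinite(vals)) or not np.isfinite(self.init_dg37):
            raise ValueError("parameter table contains non-finite values")
        for s in _STEPS:
            rc = reverse_complement(s)
            if abs(self.stack_dg37[s] - self.stack_dg37[rc]) > 1e-12:
                raise ValueError(
                    f"strand symmetry violated: ΔG({s}) != ΔG({rc})"
                )
        object.__setattr__(self, "_lut", vals)

    @classmethod
    def unified(cls) -> "NNParameterTable":
        """The unified 1 M NaCl ΔG37 set shipped with the package."""
        ref = importlib.resources.files("xspecnorm.data") / "nn_dg37_unified.tsv"
        with importlib.resources.as_file(ref) as path:
            return load_parameter_table(path)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(s, self.stack_dg37[s]) for s in _STEPS]
        rows += [("init", self.init_dg37), ("terminal_at", self.terminal_at_penalty)]
        pd.DataFrame(rows, columns=["step", "dg37_kcal_per_mol"]).to_csv(
            path, sep="\t", index=False
        )


def load_parameter_table(path: str | Path) -> NNParameterTable:
    """Read a parameter TSV with columns ``step`` and ``dg37_kcal_per_mol``.

    Rows named ``init`` and ``terminal_at`` carry the initiation term and
    the terminal A·T penalty; all other rows are dinucleotide stacks.
    """
    df = pd.read_csv(path, sep="\t", dtype={"step": str})
    vals = dict(zip(df["step"], df["dg37_kcal_per_mol"].astype(float)))
    init = vals.pop("init", 0.0)
    term_at = vals.pop("terminal_at", 0.0)
    return NNParameterTable(stack_dg37=vals, init_dg37=init, terminal_at_penalty=term_at)


_DEFAULT: NNParameterTable | None = None


def _default_table() -> NNParameterTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = NNParameterTable.unified()
    return _DEFAULT


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[arr == ord(b)] = i
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"ambiguous or invalid base {seq[pos]!r} at position {pos}"
        )
    return codes


def delta_g37(seq: str, params: NNParameterTable | None = None) -> float:
    """ΔG37 (kcal/mol) of ``seq`` hybridized to its exact complement.

    The value is the initiation term plus the sum of stacking terms over
    consecutive dinucleotide steps plus terminal A·T penalties.  Negative
    values indicate stronger binding.  Sequences must be ≥2 bases of
    unambiguous {A, C, G, T}.
    """
    params = params or _default_table()
    if len(seq) < 2:
        raise ValueError(f"sequence too short for a duplex stack: {seq!r}")
    codes = _encode(seq.upper())
    steps = 4 * codes[:-1] + codes[1:]
    g = params.init_dg37 + float(params._lut[steps].sum())
    for end in (codes[0], codes[-1]):
        if end in (0, 3):  # A or T terminal pair
            g += params.terminal_at_penalty
    return g


def delta_g37_many(
    seqs: Sequence[str] | Iterable[str],
    params: NNParameterTable | None = None,
) -> np.ndarray:
    """Vectorized ΔG37 for many sequences.

    Equal-length batches take a fast array path; mixed lengths fall back
    to the scalar routine.  Identical results to :func:`delta_g37`.
    """
    params = params or _default_table()
    seqs = list(seqs)
    if not seqs:
        return np.empty(0)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        return np.array([delta_g37(s, params) for s in seqs])
    (L,) = lengths
    if L < 2:
        raise ValueError("sequences too short for a duplex stack")
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), L)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[arr == ord(b)] = i
    if (codes < 0).any():
        row, col = np.argwhere(codes < 0)[0]
        raise ValueError(
            f"ambiguous or invalid base {seqs[row][col]!r} at position {col}"
            f" of sequence index {row}"
        )
    steps = 4 * codes[:, :-1] + codes[:, 1:]
    g = params.init_dg37 + params._lut[steps].sum(axis=1)
    at_ends = np.isin(codes[:, 0], (0, 3)).astype(float) + np.isin(
        codes[:, -1], (0, 3)
    ).astype(float)
    return g + params.terminal_at_penalty * at_ends
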
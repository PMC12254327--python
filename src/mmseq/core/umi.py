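"""Fixed-sequence UMI pool management.

The library design uses a pool (default 32) of fixed 8-base UMIs. After
enzymatic conversion the UMI on the original strand reads as its C->T
(mate 1) / G->A (mate 2) collapse while the UMI on the protected copy strand
reads unchanged, so the pool must be collision-free across all exact,
C->T-collapsed and G->A-collapsed forms for stream assignment to be
unambiguous. Every entry needs at least one C and one G so both collapsed
forms differ from the exact form.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqs import collapse_sequence

DEFAULT_POOL_SIZE = 32
UMI_LENGTH = 8


class UMIPoolError(ValueError):
    """A pool violates the collision-free / composition invariants."""


@dataclass
class UMIPool:
    umis: list[str]
    c2t_index: dict[str, str] = field(init=False)
    g2a_index: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        validate_pool(self.umis)
        self.c2t_index = {collapse_sequence(u, "C2T"): u for u in self.umis}
        self.g2a_index = {collapse_sequence(u, "G2A"): u for u in self.umis}
        self._exact = set(self.umis)

    def __len__(self) -> int:
        return len(self.umis)

    def __contains__(self, umi: str) -> bool:
        return umi in self._exact


def validate_pool(umis: list[str], umi_length: int = UMI_LENGTH) -> None:
    """Brute-force check of all exact/C2T/G2A forms for duplicates."""
    if not umis:
        raise UMIPoolError("empty UMI pool")
    for u in umis:
        if len(u) != umi_length:
            raise UMIPoolError(f"UMI {u!r} has length {len(u)}, expected {umi_length}")
        if set(u) - set("ACGT"):
            raise UMIPoolError(f"UMI {u!r} contains non-ACGT characters")
        if "C" not in u or "G" not in u:
            raise UMIPoolError(f"UMI {u!r} lacks a C or a G; collapsed forms would "
                               "not differ from the exact form")
    forms = []
    for u in umis:
        forms.append((u, "exact", u))
        forms.append((collapse_sequence(u, "C2T"), "C2T", u))
        forms.append((collapse_sequence(u, "G2A"), "G2A", u))
    for (fa, ma, ua), (fb, mb, ub) in itertools.combinations(forms, 2):
        if fa == fb:
            raise UMIPoolError(
                f"pool collision: {ma}({ua!r}) == {mb}({ub!r}) == {fa!r}")


def load_umi_pool(path: str | Path) -> UMIPool:
    """Read a one-UMI-per-line text file into a validated pool."""
    lines = [ln.strip().upper() for ln in Path(path).read_text().splitlines()]
    umis = [ln for ln in lines if ln and not ln.startswith("#")]
    return UMIPool(umis)


def generate_umi_pool(n: int = DEFAULT_POOL_SIZE, seed: int = 0,
                      umi_length: int = UMI_LENGTH, max_tries: int = 100_000) -> UMIPool:
    """Rejection-sample a collision-free pool of ``n`` UMIs.

    A pool of the default size (32) is found in well under a second; the
    theoretical packing limit for 8-mers is far higher.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    seen_forms: set[str] = set()
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise UMIPoolError(f"could not build a collision-free pool of {n}")
        cand = "".join(bases[rng.integers(0, 4, umi_length)])
        if "C" not in cand or "G" not in cand:
            continue
        forms = {cand, collapse_sequence(cand, "C2T"), collapse_sequence(cand, "G2A")}
        if len(forms) < 3 or forms & seen_forms:
            continue
        chosen.append(cand)
        seen_forms |= forms
    return UMIPool(chosen)


def default_pool() -> UMIPool:
    """The pool shipped with the package (generated, collision-free)."""
    from importlib.resources import files

    path = files("mmseq.data").joinpath("umi_pool_32.txt")
    umis = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return UMIPool(umis)
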
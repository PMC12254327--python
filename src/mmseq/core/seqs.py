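"""Small sequence utilities: conversion collapses, complements, downsampling."""
from __future__ import annotations

from collections.abc import Sequence
from typing import TypeVar

import numpy as np

_C2T = str.maketrans("Cc", "Tt")
_G2A = str.maketrans("Gg", "Aa")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

T = TypeVar("T")


def collapse_sequence(seq: str, mode: str) -> str:
    """Collapse a DNA string the way full cytosine conversion would read it.

    mode "C2T" replaces every C by T (the converted plus-sense read);
    mode "G2A" replaces every G by A (the same conversion seen on the
    reverse-complement mate). Length and all other characters are preserved.
    """
    if mode == "C2T":
        return seq.translate(_C2T)
    if mode == "G2A":
        return seq.translate(_G2A)
    raise ValueError(f"unknown collapse mode {mode!r}")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance; an N mismatches everything, including another N."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x in "Nn")


def downsample(items: Sequence[T], n: int, seed: int) -> list[T]:
    """Uniform sample of exactly ``n`` items without replacement (stable for a seed)."""
    if n > len(items):
        raise ValueError(f"cannot downsample {len(items)} items to {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(items), size=n, replace=False)
    idx.sort()
    return [items[i] for i in idx]


def quality_ok(qual: str, q_threshold: int = 20, max_unqualified_pct: float = 30.0,
               max_n: int = 10, seq: str | None = None) -> bool:
    """Basic read filter: too many low-quality bases or Ns fails the read.

    Mirrors the common ``-q 20 -u 30 -n 10`` semantics (a base under Q20 is
    unqualified; a read with >30% unqualified bases or >10 Ns is dropped).
    """
    if not qual:
        return False
    low = sum(1 for ch in qual if ord(ch) - 33 < q_threshold)
    if 100.0 * low / len(qual) > max_unqualified_pct:
        return False
    if seq is not None and seq.upper().count("N") > max_n:
        return False
    return True
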
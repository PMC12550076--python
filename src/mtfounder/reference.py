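"""Synthetic stand-in for the rCRS mitochondrial reference sequence.

The pipeline expresses every haplotype as a set of variants against the
16,569-bp revised Cambridge Reference Sequence coordinate system.  This
module provides a *synthetic* reference of the correct length and roughly
rCRS-like base composition, generated deterministically, with the handful
of bases the analysis logic actually depends on pinned to their true rCRS
values:

* position 3107 is ``N`` (the rCRS placeholder, always masked),
* position 16247 is ``A`` (so the classic Polynesian-motif defining
  variant 16247G is an A->G transition),
* position 14022 is ``A`` (so 14022G is likewise a transition).

Variant classification, simulation and FASTA diffing are all performed
against the same reference object, so the pipeline is self-consistent.
Users working with real mitogenomes should pass the genuine rCRS sequence
(e.g. read from a FASTA file) to the ``reference=`` parameters exposed
throughout the package.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Length of the rCRS coordinate system (1-based positions 1..16569).
MT_LENGTH = 16569

#: Approximate rCRS base composition used to draw the synthetic sequence.
_BASE_FREQS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}

#: Bases pinned to their true rCRS values (1-based position -> base).
#: 310 sits inside the poly-C stretch where allele-specific masking applies.
_PINNED = {310: "T", 312: "T", 3107: "N", 14022: "A", 16247: "A"}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

_SEED = 16569  # fixed: the reference is a package constant, not a dial


@lru_cache(maxsize=1)
def reference_sequence() -> str:
    """Return the packaged synthetic reference as an upper-case string."""
    rng = np.random.default_rng(_SEED)
    bases = np.array(list(_BASE_FREQS), dtype="U1")
    probs = np.array(list(_BASE_FREQS.values()))
    probs = probs / probs.sum()
    seq = rng.choice(bases, size=MT_LENGTH, p=probs)
    for pos, base in _PINNED.items():
        seq[pos - 1] = base
    return "".join(seq)


def reference_base(position: int, reference: str | None = None) -> str:
    """1-based lookup of the reference base at *position*."""
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
    seq = reference if reference is not None else reference_sequence()
    return seq[position - 1]


def transition_partner(base: str) -> str | None:
    """Return the transition partner of *base* (A<->G, C<->T), or None."""
    return _TRANSITION.get(base.upper())


def write_reference_fasta(path, reference: str | None = None) -> None:
    """Write the reference to *path* as single-record FASTA."""
    seq = reference if reference is not None else reference_sequence()
    with open(path, "w") as fh:
        fh.write(">synthetic_rCRS_standin length=16569\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
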
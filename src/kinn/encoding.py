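"""Numeric encodings of gRNA-DNA alignments.

Two representations are supported:

* the **in vivo 13-channel encoding**: a fixed ``25 x 13`` binary matrix
  covering 3 PAM positions, 20 guide positions and 2 insertion-padding
  columns, with channel blocks [guide one-hot (4) | substitution one-hot
  (4) | insertion one-hot (4) | deletion bit (1)].  Unused padding columns
  are all-zero ("N" columns).
* the **pairing encoding** used by the in vitro simulator: an ``L x 4``
  one-hot of the *pairing class* at each position — complementary, or one
  of three mismatch identities (the target base's rank among the
  non-complementary bases in A<C<G<T order).

Column layout of the 25-position matrix is PAM-proximal first:
``[PAM(3) | guide(20) | padding(2)]``.  Guide position ``p`` (0-based)
therefore lives at column ``3 + p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EncodingError, StructuralError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# Watson-Crick DNA complement of the DNA base written for an RNA guide base
# (U is treated as T throughout).
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ALIGNMENT_COLUMNS = 25
N_CHANNELS = 13
PAM_LENGTH = 3
GUIDE_LENGTH = 20
_GUIDE_SLICE = slice(0, 4)
_SUBST_SLICE = slice(4, 8)
_INSERT_SLICE = slice(8, 12)
_DELETION_CHANNEL = 12


def canonical_base(c: str) -> str:
    b = c.upper().replace("U", "T")
    if b not in "ACGT-":
        raise EncodingError(f"illegal character {c!r}; alphabet is A/C/G/T/U/-")
    return b


def canonical_sequence(seq: str) -> str:
    return "".join(canonical_base(c) for c in seq)


def complement(base: str) -> str:
    return _COMPLEMENT[canonical_base(base)]


def pairing_class(guide_base: str, target_base: str) -> int:
    """0 = complementary; 1..3 = rank of the target base among the three
    non-complementary bases (A<C<G<T)."""
    g = canonical_base(guide_base)
    t = canonical_base(target_base)
    comp = _COMPLEMENT[g]
    if t == comp:
        return 0
    mismatches = [b for b in BASES if b != comp]
    return 1 + mismatches.index(t)


def class_to_target(guide_base: str, cls: int) -> str:
    comp = _COMPLEMENT[canonical_base(guide_base)]
    if cls == 0:
        return comp
    return [b for b in BASES if b != comp][cls - 1]


@dataclass(frozen=True)
class GuideTargetAlignment:
    """A pre-aligned gRNA-target pair.

    ``target`` is aligned against ``pam + guide``: one character per
    alignment column, ``-`` marking a deletion in the target.  Insertions
    (extra target bases with no guide counterpart) are described by
    ``guide_alignment`` — the ``pam + guide`` string with ``-`` at
    insertion columns; when ``None`` the alignment has no insertions and
    ``target`` must have exactly ``PAM_LENGTH + len(guide)`` columns.
    """

    guide: str
    pam: str
    target: str
    guide_alignment: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "guide", canonical_sequence(self.guide))
        object.__setattr__(self, "pam", canonical_sequence(self.pam))
        object.__setattr__(self, "target", canonical_sequence(self.target))
        if len(self.pam) != PAM_LENGTH:
            raise EncodingError(f"PAM must have {PAM_LENGTH} nt")
        if len(self.guide) != GUIDE_LENGTH:
            raise EncodingError(f"guide must have {GUIDE_LENGTH} nt")
        if self.guide_alignment is not None:
            ga = canonical_sequence(self.guide_alignment)
            object.__setattr__(self, "guide_alignment", ga)
            if ga.replace("-", "") != self.pam + self.guide:
                raise EncodingError("guide_alignment must spell pam+guide plus gaps")
            if len(ga) != len(self.target):
                raise EncodingError("guide_alignment and target lengths differ")
        elif len(self.target) != PAM_LENGTH + GUIDE_LENGTH:
            raise EncodingError(
                "target length must equal PAM+guide length when no insertions"
            )

    @property
    def columns(self) -> list[tuple[str, str]]:
        ga = self.guide_alignment or (self.pam + self.guide)
        return list(zip(ga, self.target))

    def n_insertions(self) -> int:
        return 0 if self.guide_alignment is None else self.guide_alignment.count("-")


@dataclass(frozen=True)
class EncodedAlignment:
    """Numeric alignment representation (one or both encodings filled)."""

    matrix: np.ndarray | None = None          # (25, 13) in vivo encoding
    pairing_matrix: np.ndarray | None = None  # (L, 4) pairing classes
    guide: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.matrix is not None:
            m = np.asarray(self.matrix, dtype=float)
            if m.shape != (ALIGNMENT_COLUMNS, N_CHANNELS):
                raise StructuralError(
                    f"in vivo encoding must be {(ALIGNMENT_COLUMNS, N_CHANNELS)}, "
                    f"got {m.shape}"
                )
            object.__setattr__(self, "matrix", m)
        if self.pairing_matrix is not None:
            p = np.asarray(self.pairing_matrix, dtype=float)
            if p.ndim != 2 or p.shape[1] != 4:
                raise StructuralError("pairing matrix must be (L, 4)")
            object.__setattr__(self, "pairing_matrix", p)


def encode_invivo(alignment: GuideTargetAlignment) -> EncodedAlignment:
    """25 x 13 binary encoding of a pre-aligned pair.

    The target is written protospacer-strand, i.e. in the guide's
    orientation, so a perfect match means target base == guide base
    (U read as T).  Per column: the guide block one-hot encodes the guide
    (or PAM) base; the substitution block fires only where the target base
    differs from the guide base (both present); the insertion block
    one-hot encodes target bases with no guide counterpart; the deletion
    bit marks target gaps.  Columns past the alignment stay all-zero.
    """
    cols = alignment.columns
    if len(cols) > ALIGNMENT_COLUMNS:
        raise EncodingError(
            f"alignment has {len(cols)} columns; at most {ALIGNMENT_COLUMNS} "
            f"({PAM_LENGTH} PAM + {GUIDE_LENGTH} guide + "
            f"{ALIGNMENT_COLUMNS - PAM_LENGTH - GUIDE_LENGTH} insertion padding)"
        )
    m = np.zeros((ALIGNMENT_COLUMNS, N_CHANNELS))
    consumed = 0  # non-gap guide/PAM characters seen so far
    for col, (g, t) in enumerate(cols):
        if g == "-":                       # insertion: target base, no guide base
            if t == "-":
                raise EncodingError(f"column {col}: gap aligned to gap")
            m[col, _INSERT_SLICE][_BASE_INDEX[t]] = 1.0
            continue
        consumed += 1
        m[col, _GUIDE_SLICE][_BASE_INDEX[g]] = 1.0
        if t == "-":                       # deletion in target
            m[col, _DELETION_CHANNEL] = 1.0
            continue
        if t != g:
            m[col, _SUBST_SLICE][_BASE_INDEX[t]] = 1.0
    return EncodedAlignment(matrix=m, guide=alignment.guide,
                            provenance=alignment.provenance)


def decode_invivo(encoded: EncodedAlignment) -> GuideTargetAlignment:
    """Inverse of :func:`encode_invivo` on canonical alignments."""
    m = encoded.matrix
    if m is None:
        raise StructuralError("no in vivo matrix to decode")
    guide_cols: list[str] = []
    target_cols: list[str] = []
    for col in range(ALIGNMENT_COLUMNS):
        row = m[col]
        if not row.any():
            continue                        # padding column
        ins = row[_INSERT_SLICE]
        if ins.any():
            guide_cols.append("-")
            target_cols.append(BASES[int(np.argmax(ins))])
            continue
        g = BASES[int(np.argmax(row[_GUIDE_SLICE]))]
        guide_cols.append(g)
        if row[_DELETION_CHANNEL]:
            target_cols.append("-")
        elif row[_SUBST_SLICE].any():
            target_cols.append(BASES[int(np.argmax(row[_SUBST_SLICE]))])
        else:
            target_cols.append(g)
    ga = "".join(guide_cols)
    flat = ga.replace("-", "")
    return GuideTargetAlignment(
        guide=flat[PAM_LENGTH:],
        pam=flat[:PAM_LENGTH],
        target="".join(target_cols),
        guide_alignment=ga if "-" in ga else None,
        provenance=encoded.provenance,
    )


def encode_pairing(guide_like: str, target_like: str, L: int = 50) -> EncodedAlignment:
    """L x 4 one-hot of the pairing class at each position."""
    g = canonical_sequence(guide_like)
    t = canonical_sequence(target_like)
    if len(g) != len(t):
        raise StructuralError(
            f"sequence lengths differ: {len(g)} vs {len(t)}"
        )
    if len(g) != L:
        raise StructuralError(f"expected sequences of length {L}, got {len(g)}")
    mat = np.zeros((L, 4))
    for i, (gb, tb) in enumerate(zip(g, t)):
        mat[i, pairing_class(gb, tb)] = 1.0
    return EncodedAlignment(pairing_matrix=mat, guide=g)


def decode_pairing(encoded: EncodedAlignment) -> tuple[str, str]:
    """Recover (guide, target) from a pairing matrix plus stored guide."""
    if encoded.pairing_matrix is None or encoded.guide is None:
        raise StructuralError("pairing decode needs the matrix and the guide")
    classes = np.argmax(encoded.pairing_matrix, axis=1)
    target = "".join(
        class_to_target(gb, int(c)) for gb, c in zip(encoded.guide, classes)
    )
    return encoded.guide, target
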
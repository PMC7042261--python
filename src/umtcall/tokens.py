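"""Per-position allele tokens for an insert read against its amplicon reference.

SNVs and indels are folded into one per-position vocabulary so the same
unanimity rule covers both. For a reference insert of length L, every read
is summarized by its *deviations*: a sorted tuple of ``(pos0, token)``
pairs at the 0-based insert positions where the read differs from the
reference. Positions absent from the deviation list carry the reference
base.

Token grammar (all uppercase):

``B``        substitution: base ``B`` observed at the position
``B+SEQ``    base ``B`` followed by an insertion of ``SEQ``
``B-k``      base ``B`` followed by a k-base deletion (anchor position)
``*``        position spanned by a deletion anchored upstream
``N``        no-call at the position

Indel tokens are anchored on the base preceding the event (VCF-style
anchoring). Alignments come from global pairwise alignment with affine
gap penalties, so a multi-base indel stays one contiguous event instead
of fragmenting into co-optimal scattered gaps; placement within a repeat
follows the aligner's deterministic (leftmost) path.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

Deviations = tuple[tuple[int, str], ...]

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -7
_aligner.extend_gap_score = -0.25


@lru_cache(maxsize=2_000_000)
def read_deviations(ref: str, seq: str) -> Deviations:
    """Deviation tuple of ``seq`` against reference insert ``ref``.

    Cached: amplicon sequencing produces the same insert strings many
    times over, so tokenization cost is paid once per distinct sequence.
    """
    if seq == ref:
        return ()
    if len(seq) == len(ref):
        # No indel possible at equal length under edit-distance alignment
        # unless a same-length complex event is cheaper; plain positional
        # comparison is the correct token reading for substitutions.
        return tuple(
            (i, b) for i, (a, b) in enumerate(zip(ref, seq)) if a != b
        )
    return _aligned_deviations(ref, seq)


def _aligned_deviations(ref: str, seq: str) -> Deviations:
    coords = _aligner.align(ref, seq)[0].coordinates
    tokens: dict[int, str] = {}
    for col in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, col]), int(coords[0, col + 1])
        q0, q1 = int(coords[1, col]), int(coords[1, col + 1])
        if r1 > r0 and q1 > q0:  # aligned block: substitutions only
            for i in range(r1 - r0):
                if ref[r0 + i] != seq[q0 + i]:
                    tokens[r0 + i] = seq[q0 + i]
        elif q1 > q0:  # insertion in the read, anchored on previous ref base
            anchor = max(r0 - 1, 0)
            base = tokens.get(anchor, ref[anchor])
            tokens[anchor] = _add_insertion(base, seq[q0:q1])
        elif r1 > r0:  # deletion from the read
            anchor = max(r0 - 1, 0)
            base = tokens.get(anchor, ref[anchor])
            tokens[anchor] = _add_deletion(base, r1 - r0)
            for i in range(r0, r1):
                tokens[i] = "*"
    return tuple(
        (pos, tok) for pos, tok in sorted(tokens.items()) if tok != ref[pos]
    )


def _add_insertion(base_token: str, ins: str) -> str:
    # Compose with an existing deletion suffix if present: B-k -> B+SEQ-k
    if "-" in base_token:
        head, k = base_token.split("-")
        return f"{head}+{ins}-{k}"
    return f"{base_token}+{ins}"


def _add_deletion(base_token: str, k: int) -> str:
    if "-" in base_token:  # adjacent deletions merge
        head, k0 = base_token.split("-")
        return f"{head}-{int(k0) + k}"
    return f"{base_token}-{k}"


def split_token(token: str) -> tuple[str, str, int]:
    """Decompose a token into (base, inserted_seq, deleted_len)."""
    if token in ("*", "N"):
        return token, "", 0
    dele = 0
    if "-" in token:
        token, k = token.split("-")
        dele = int(k)
    ins = ""
    if "+" in token:
        token, ins = token.split("+")
    return token, ins, dele


def token_alleles(
    pos0: int, token: str, ref: str
) -> tuple[int, str, str, str] | None:
    """Translate a deviation token into a VCF-style allele.

    Returns ``(pos0_anchor, ref_allele, alt_allele, variant_class)`` with
    class one of SNV/INS/DEL, or ``None`` for tokens that carry no allele
    of their own (``*`` spanning-deletion placeholders and ``N`` no-calls).
    """
    if token in ("*", "N"):
        return None
    base, ins, dele = split_token(token)
    if dele > 0:
        ref_allele = ref[pos0 : pos0 + dele + 1]
        alt_allele = base + ins
        return pos0, ref_allele, alt_allele, "DEL"
    if ins:
        return pos0, ref[pos0], base + ins, "INS"
    return pos0, ref[pos0], base, "SNV"
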
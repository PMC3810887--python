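"""Small DNA string utilities shared across modules."""

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

VALID_BASES = frozenset("ACGTN")
UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def rotations(seq: str) -> list[str]:
    """All cyclic rotations of ``seq`` (length of the list = len(seq))."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def longest_run(seq: str) -> int:
    """Length of the longest run of identical characters (0 for empty input)."""
    best = 0
    cur = 0
    prev = None
    for ch in seq:
        cur = cur + 1 if ch == prev else 1
        prev = ch
        if cur > best:
            best = cur
    return best
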
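"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most naive route available
(full enumeration, plain string splicing) and share no logic with the
implementation they check.
"""

from hackdesign.genome_io import revcomp

SPACER = 20


def brute_force_scan(seq: str, junction: int, window: int):
    """Enumerate every spacer+NGG site whose spacer is inside the window.

    Plus-strand sites are found by direct enumeration; minus-strand
    sites by scanning the reverse complement with the same plus-strand
    rule and mapping coordinates back.  Returns a set of
    (spacer, strand, cut) tuples.
    """
    n = len(seq)
    lo, hi = max(0, junction - window), min(n, junction + window)
    out = set()
    for p in range(SPACER, n - 2):
        if seq[p + 1 : p + 3] == "GG" and p - SPACER >= lo and p <= hi:
            out.add((seq[p - SPACER : p], "+", p - 3))
    rc = revcomp(seq)
    for p in range(SPACER, n - 2):
        if rc[p + 1 : p + 3] == "GG":
            # rc[p-20:p) maps to plus-strand interval [n-p, n-p+20)
            s_plus, e_plus = n - p, n - p + SPACER
            if s_plus >= lo and e_plus <= hi:
                cut = n - (p - 3)
                out.add((rc[p - SPACER : p], "-", cut))
    return out


def brute_force_match_count(sequences, spacer: str) -> int:
    """Sliding-window count of spacer+NGG over every strand position."""
    total = 0
    for seq in sequences:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - SPACER - 2):
                if (
                    s[i : i + SPACER] == spacer
                    and s[i + SPACER + 1 : i + SPACER + 3] == "GG"
                ):
                    total += 1
    return total


def splice_insert(contig: str, junction: int, insert: str, strand: str) -> str:
    """Plus-strand contig after inserting ``insert`` (gene orientation)
    at the junction — the naive string-splice oracle for integration."""
    if strand == "+":
        return contig[:junction] + insert + contig[junction:]
    return contig[:junction] + revcomp(insert) + contig[junction:]
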
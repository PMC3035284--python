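"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written from first principles (plain string scanning, no
imports from the package's structural internals) so agreement with the
package is a two-route check, not a tautology.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}  # bacterial code (NCBI table 11)


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def oracle_orfs(
    seq: str,
    min_nt: int = 180,
    max_masked: int = 30,
    min_unmasked: int = 150,
) -> set[tuple]:
    """Enumerate retained ORFs by direct stop scanning in all six frames.

    Returns tuples (fwd_start, fwd_end, strand, frame, trunc5, trunc3,
    masked_nt) with spans excluding the terminal stop codon; edge-runoff
    spans extend to the sequence end including a partial codon.
    """
    L = len(seq)
    masked = [c.islower() for c in seq]
    out: set[tuple] = set()
    for strand in "+-":
        s = seq.upper() if strand == "+" else rc(seq)
        for off in range(3):
            runs = []
            run_start = off
            p = off
            while p + 3 <= L:
                if s[p : p + 3] in _STOPS:
                    runs.append((run_start, p, run_start == off, False))
                    run_start = p + 3
                p += 3
            runs.append((run_start, L, run_start == off, True))
            for a, b, t5, t3 in runs:
                span = b - a
                if span < min_nt:
                    continue
                f0, f1 = (a, b) if strand == "+" else (L - b, L - a)
                m = sum(masked[f0:f1])
                if m > max_masked or span - m < min_unmasked:
                    continue
                out.add((f0, f1, strand, off + 1, t5, t3, m))
    return out


def orf_call_key(call) -> tuple:
    """Project an OrfCall onto the oracle's tuple shape."""
    return (
        call.interval.start,
        call.interval.end,
        call.strand,
        call.frame,
        call.truncated_5p,
        call.truncated_3p,
        call.masked_nt,
    )
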
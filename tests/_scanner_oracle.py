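"""Independent brute-force oracle for the miR-430 site scanner.

Enumerates every motif occurrence position by position, then resolves
overlaps by repeatedly selecting the longest remaining candidate (leftmost
on ties) and discarding everything that overlaps it.  Kept deliberately
naive and separate from the package implementation.
"""

MOTIFS = {
    "6mer": "GCACTT",
    "s6mer-O": "AGCACT",
    "7mer-A1": "GCACTTA",
    "7mer-M8": "AGCACTT",
    "8mer": "AGCACTTA",
}


def oracle_scan(seq: str) -> list[tuple[str, int, int]]:
    seq = seq.upper()
    candidates = []
    for site_type, motif in MOTIFS.items():
        m = len(motif)
        for i in range(len(seq) - m + 1):
            if seq[i : i + m] == motif:
                candidates.append((site_type, i, i + m))
    kept = []
    remaining = list(candidates)
    while remaining:
        best = None
        for c in remaining:
            if best is None:
                best = c
            else:
                if (c[2] - c[1], -c[1]) > (best[2] - best[1], -best[1]):
                    best = c
        kept.append(best)
        remaining = [c for c in remaining if c[2] <= best[1] or c[1] >= best[2]]
    kept.sort(key=lambda c: c[1])
    return kept
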
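"""Independent brute-force oracles, written directly from the event/ORF
definitions with no shared code with the implementation."""
from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}


def introns_of(exons):
    return [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]


def brute_force_events(gene):
    """Enumerate (event_type, signature) over all ordered isoform pairs."""
    found = set()
    txs = gene.transcripts
    all_exon_sets = [set(t.exons) for t in txs]
    for a in txs:
        ia = introns_of(a.exons)
        ea = set(a.exons)
        for b in txs:
            if a is b:
                continue
            ib = introns_of(b.exons)
            eb = set(b.exons)
            # IR: intron of a inside a single exon of b
            for (s, e) in ia:
                if any(xs <= s - 1 and e + 1 <= xe for xs, xe in b.exons):
                    found.add(("IR", (s, e)))
            # ES: internal exon of a whose flanking introns fuse in b
            for j in range(1, len(a.exons) - 1):
                ex = a.exons[j]
                d0 = ia[j - 1][0]
                a1 = ia[j][1]
                if (d0, a1) in ib:
                    found.add(("ES", (ex[0], ex[1], d0, a1)))
            # alt splice sites: one shared boundary, flanking exons overlap
            for (s1, e1) in ia:
                for (s2, e2) in ib:
                    if s1 == s2 and e1 != e2:
                        down_a = next(x for x in a.exons if x[0] == e1 + 1)
                        down_b = next(x for x in b.exons if x[0] == e2 + 1)
                        if down_a[0] <= down_b[1] and down_b[0] <= down_a[1]:
                            t = "A3SS" if gene.strand == "+" else "A5SS"
                            found.add((t, (min(e1, e2), max(e1, e2), s1)))
                    if e1 == e2 and s1 != s2:
                        up_a = next(x for x in a.exons if x[1] == s1 - 1)
                        up_b = next(x for x in b.exons if x[1] == s2 - 1)
                        if up_a[0] <= up_b[1] and up_b[0] <= up_a[1]:
                            t = "A5SS" if gene.strand == "+" else "A3SS"
                            found.add((t, (min(s1, s2), max(s1, s2), e1)))
            # MEE: internal exons, one per isoform, same outer boundaries
            for j in range(1, len(a.exons) - 1):
                e1x = a.exons[j]
                if e1x in eb:
                    continue
                for k in range(1, len(b.exons) - 1):
                    e2x = b.exons[k]
                    if e2x in ea or not (e1x[1] < e2x[0] or e2x[1] < e1x[0]):
                        continue
                    if ia[j - 1][0] != ib[k - 1][0] or ia[j][1] != ib[k][1]:
                        continue
                    if any(e1x in es and e2x in es for es in all_exon_sets):
                        continue
                    lo, hi = sorted((e1x, e2x))
                    found.add(
                        ("MEE", (lo[0], lo[1], hi[0], hi[1], ia[j - 1][0], ia[j][1]))
                    )
    return found


def brute_force_longest_orf(seq):
    """Scan every (start, frame) pair; return (start, stop_last_base) or None."""
    seq = seq.upper()
    best = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        pos = start
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if codon in STOPS and pos > start:
                length = pos + 3 - start
                key = (length, -start)
                if best is None or key > best[0]:
                    best = (key, (start, pos + 2))
                break
            pos += 3
    return None if best is None else best[1]


def brute_force_bh(pvals):
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = pvals[i] * n / rank_from_end
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj
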
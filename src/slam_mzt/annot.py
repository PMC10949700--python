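"""3'UTR annotation: main-isoform selection and miR-430 target-site scanning.

miR-430 represses targets through seed matches in the 3'UTR.  Five canonical
site types are recognised, from the weakest 6mer seed match to the full 8mer
(an A opposite miRNA position 1 plus a match to position 8):

====== ==========
type   motif
====== ==========
6mer     GCACTT
s6mer-O  AGCACT
7mer-A1  GCACTTA
7mer-M8  AGCACTT
8mer     AGCACTTA
====== ==========

Overlapping matches at one locus are collapsed so that only the longest site
is reported (a reported 8mer suppresses the 6mer/7mer matches nested in it).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: site type -> seed-match motif on the mRNA sense strand
MIR430_MOTIFS: dict[str, str] = {
    "6mer": "GCACTT",
    "s6mer-O": "AGCACT",
    "7mer-A1": "GCACTTA",
    "7mer-M8": "AGCACTT",
    "8mer": "AGCACTTA",
}

SITE_TYPES = tuple(MIR430_MOTIFS)


@dataclass(frozen=True)
class Mir430Site:
    """A single miR-430 seed match on a 3'UTR (0-based, half-open)."""

    site_type: str
    motif: str
    start: int
    end: int


def _find_all(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``motif`` in ``seq``."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_mir430_sites(utr_sequence: str) -> list[Mir430Site]:
    """Scan a 3'UTR sense-strand sequence for miR-430 seed matches.

    All occurrences of the five motifs are enumerated; among overlapping
    candidates only the longest site is kept (equal lengths: leftmost;
    chained overlaps are resolved greedily by descending length then
    position).  ``N`` never matches.  Returns sites sorted by start.
    """
    seq = utr_sequence.upper()
    candidates = [
        Mir430Site(site_type, motif, s, s + len(motif))
        for site_type, motif in MIR430_MOTIFS.items()
        for s in _find_all(seq, motif)
    ]
    # longest first, then leftmost; greedy non-overlap selection
    candidates.sort(key=lambda c: (-(c.end - c.start), c.start))
    kept: list[Mir430Site] = []
    for cand in candidates:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept


def count_sites_by_type(sites: list[Mir430Site]) -> dict:
    """Per-type site counts after overlap resolution, plus a has_site flag."""
    counts = {t: 0 for t in SITE_TYPES}
    for s in sites:
        counts[s.site_type] += 1
    counts["has_site"] = any(counts[t] > 0 for t in SITE_TYPES)
    return counts


def site_count_table(utr_sequences: dict[str, str]) -> pd.DataFrame:
    """Scan every gene's UTR and tabulate per-type site counts.

    Returns a DataFrame indexed by gene_id with one column per site type
    plus a boolean ``has_site`` column.
    """
    rows = {}
    for gene_id, seq in utr_sequences.items():
        rows[gene_id] = count_sites_by_type(scan_mir430_sites(seq))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df[list(SITE_TYPES) + ["has_site"]]


def target_status(
    has_site: bool,
    gene_id: str,
    known_targets: set[str] | frozenset[str] = frozenset(),
    control_nontargets: set[str] | frozenset[str] = frozenset(),
) -> str:
    """Label a gene as known_target / control_nontarget / putative_target / others.

    Known targets and control non-targets come from prior loss-of-function
    gene lists supplied as plain-text inputs; putative targets are genes with
    at least one scanned site that are not on the known list.
    """
    if gene_id in known_targets:
        return "known_target"
    if gene_id in control_nontargets:
        return "control_nontarget"
    if has_site:
        return "putative_target"
    return "others"


@dataclass(frozen=True)
class IsoformAssignment:
    gene_id: str
    chosen_utr_id: str
    proportion: float
    flag: str  # "", "tie", or "low_confidence"


def select_main_isoform(
    isoform_counts: pd.DataFrame,
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Pick one main 3'UTR isoform per gene by read support.

    Parameters
    ----------
    isoform_counts
        Columns ``isoform_id``, ``gene_id``, ``reads`` where ``reads`` is the
        isoform's read total summed over the reference timepoints (defaults
        in the pipeline: 2 h and 7 h).
    lengths
        Optional isoform lengths, used to break the zero-read case in favour
        of the longest isoform (flagged low_confidence).

    The chosen isoform maximises summed reads; exact ties go to the
    lexicographically smaller isoform id and are flagged.  All of the gene's
    reads are subsequently re-assigned to the chosen isoform.
    """
    out = []
    for gene_id, grp in isoform_counts.groupby("gene_id", sort=True):
        total = grp["reads"].sum()
        if total <= 0:
            if lengths is not None:
                cand = grp.assign(_len=grp["isoform_id"].map(lengths))
                cand = cand.sort_values(["_len", "isoform_id"], ascending=[False, True])
            else:
                cand = grp.sort_values("isoform_id")
            out.append(IsoformAssignment(gene_id, cand["isoform_id"].iloc[0], 1.0, "low_confidence"))
            continue
        best = grp["reads"].max()
        winners = sorted(grp.loc[grp["reads"] == best, "isoform_id"])
        flag = "tie" if len(winners) > 1 else ""
        out.append(IsoformAssignment(gene_id, winners[0], float(best / total), flag))
    return pd.DataFrame([vars(a) for a in out])
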
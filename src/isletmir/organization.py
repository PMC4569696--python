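"""Seed sequences, seed families, genomic clusters, and 7mer-m8 site scans.

The seed is nucleotides 2-8 of the mature miRNA (7 nt, 1-based inclusive) —
the standard target-recognition determinant.  miRNAs sharing an identical
seed form a family; miRNAs transcribed from nearby loci on the same
chromosome and strand (gap <= 10 kb by default, single-linkage) form a
genomic cluster, emulating polycistronic precursors.  The site scan finds
exact reverse-complement seed matches (7mer-m8-style) and exists to verify
planted synthetic targets, not to predict real ones.
"""

from __future__ import annotations

from typing import Sequence

from .counts_io import MiRNAAnnotation

RNA_ALPHABET = set("ACGU")
_RC = {"A": "U", "C": "G", "G": "C", "U": "A"}


def seed_sequence(mature: str, dna_ok: bool = False) -> str:
    """Nucleotides 2-8 (1-based inclusive) of a mature miRNA sequence.

    ``dna_ok=True`` accepts T and converts to U before extraction.
    """
    seq = mature.upper()
    if dna_ok:
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        hint = " (pass dna_ok=True to convert T->U)" if bad == {"T"} else ""
        raise ValueError(f"non-RNA letters {sorted(bad)} in sequence{hint}")
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short for a seed: {len(seq)} nt < 8")
    return seq[1:8]


def reverse_complement(rna: str) -> str:
    bad = set(rna.upper()) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA letters {sorted(bad)}")
    return "".join(_RC[c] for c in reversed(rna.upper()))


def assign_seeds(annotations: Sequence[MiRNAAnnotation], dna_ok: bool = False) -> None:
    for a in annotations:
        a.seed = seed_sequence(a.mature_sequence, dna_ok=dna_ok)


def group_families(annotations: Sequence[MiRNAAnnotation]) -> list[MiRNAAnnotation]:
    """Set family_id: identical iff seeds identical.

    The family id is the lexicographically smallest member name, so the
    partition is deterministic and invariant to input order.  Seeds are
    computed on the fly if unset.
    """
    for a in annotations:
        if a.seed is None:
            a.seed = seed_sequence(a.mature_sequence)
    by_seed: dict[str, list[MiRNAAnnotation]] = {}
    for a in annotations:
        by_seed.setdefault(a.seed, []).append(a)
    for members in by_seed.values():
        fam = min(m.mirna_id for m in members)
        for m in members:
            m.family_id = fam
    return list(annotations)


def group_clusters(
    annotations: Sequence[MiRNAAnnotation], max_gap_bp: int = 10000
) -> list[MiRNAAnnotation]:
    """Set cluster_id by single-linkage chaining of nearby loci.

    Two loci on the same chromosome and strand join when the gap from the
    end of the earlier locus to the start of the later one (0-based
    half-open coordinates) is <= ``max_gap_bp``; transitive closure defines
    the clusters.  Cluster ids are the lexicographically smallest member
    name, making assignment order-invariant.
    """
    groups: dict[tuple[str, str], list[MiRNAAnnotation]] = {}
    for a in annotations:
        groups.setdefault((a.chrom, a.strand), []).append(a)
    for members in groups.values():
        members.sort(key=lambda a: (a.start, a.end, a.mirna_id))
        chains: list[list[MiRNAAnnotation]] = []
        chain_end = None
        for a in members:
            if chain_end is not None and a.start - chain_end <= max_gap_bp:
                chains[-1].append(a)
                chain_end = max(chain_end, a.end)
            else:
                chains.append([a])
                chain_end = a.end
        for chain in chains:
            cid = min(m.mirna_id for m in chain)
            for m in chain:
                m.cluster_id = cid
    return list(annotations)


def scan_seed_matches(utr: str, seed: str) -> list[int]:
    """0-based start positions of the reverse complement of ``seed`` in ``utr``.

    Overlapping occurrences are all reported.  This is an exact 7-nt match
    scan (7mer-m8-style site); wobble pairs and 3' compensatory sites are
    out of scope.
    """
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    site = reverse_complement(seed)
    u = utr.upper()
    bad = set(u) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA letters {sorted(bad)} in UTR")
    hits = []
    pos = u.find(site)
    while pos != -1:
        hits.append(pos)
        pos = u.find(site, pos + 1)
    return hits
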
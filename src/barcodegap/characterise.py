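"""Per-species molecular characterisation.

For each species this module produces the four quantities a barcode reference
entry reports: sample size, the maximum intraspecific p-distance, the minimum
distance to any other species together with that nearest neighbour's name, and
an IUPAC consensus barcode.  The pair of distance bounds is the species'
barcode gap: delimitation by a fixed threshold is only trustworthy where
max-intra stays below min-inter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix, DistancePolicy, distance_matrix
from .seqio import IUPAC_SETS, SET_TO_IUPAC, Alignment


@dataclass
class SpeciesProfile:
    """One species' molecular characterisation.

    ``max_intra`` is ``None`` (not applicable) exactly when the species has a
    single record.  ``consensus`` is gap-free: all-gap columns are dropped.
    """

    species: str
    n: int
    max_intra: float | None
    min_inter: float
    nearest_species: str
    consensus: str


def _species_indices(m: DistanceMatrix, labels: Mapping[str, str], sp: str) -> list[int]:
    idx = [i for i, rid in enumerate(m.ids) if labels.get(rid) == sp]
    if not idx:
        raise KeyError(f"species {sp!r} has no records in the matrix")
    return idx


def max_intraspecific(
    m: DistanceMatrix, labels: Mapping[str, str], sp: str
) -> float | None:
    """Largest p-distance among records of one species; None when n = 1."""
    idx = _species_indices(m, labels, sp)
    if len(idx) == 1:
        return None
    sub = m.d[np.ix_(idx, idx)]
    return float(np.nanmax(sub))


def min_interspecific(
    m: DistanceMatrix, labels: Mapping[str, str], sp: str
) -> tuple[float, str]:
    """Smallest p-distance from any record of ``sp`` to another species' record.

    Returns ``(distance, nearest_species)``; equidistant neighbours are broken
    lexicographically by species name so that reports are deterministic.
    """
    idx = _species_indices(m, labels, sp)
    others = [(i, labels[m.ids[i]]) for i, rid in enumerate(m.ids)
              if labels.get(m.ids[i]) != sp]
    if not others:
        raise ValueError("minimum interspecific distance needs at least 2 species")
    best: tuple[float, str] | None = None
    for i in idx:
        for j, other_sp in others:
            dij = m.d[i, j]
            if np.isnan(dij):
                continue
            cand = (float(dij), other_sp)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise ValueError(f"all cross-species distances undefined for {sp!r}")
    return best


def consensus_sequence(seqs: Sequence[str], majority: float = 0.5) -> str:
    """IUPAC majority consensus of equal-length aligned sequences.

    Per column: gaps are ignored (an all-gap column is dropped from the
    output); ambiguity codes contribute their base sets to the observed pool
    but not to the majority vote.  A base wins the column when it is the
    unique most frequent unambiguous call and its share of the unambiguous
    calls is at least ``majority``; otherwise the minimal IUPAC code covering
    every observed base is emitted, so a 1:1 tie like {C, T} becomes Y.
    """
    if not seqs:
        raise ValueError("consensus of empty input")
    if not 0.5 <= majority <= 1.0:
        raise ValueError("majority threshold must lie in [0.5, 1.0]")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("consensus input sequences differ in length")
    out: list[str] = []
    for col in range(length):
        chars = [s[col] for s in seqs if s[col] != "-"]
        if not chars:
            continue  # all-gap column dropped
        plain = Counter(c for c in chars if c in "ACGT")
        observed: set[str] = set()
        for c in chars:
            observed |= IUPAC_SETS[c]
        if plain:
            top, top_n = plain.most_common(1)[0]
            unique_top = sum(1 for v in plain.values() if v == top_n) == 1
            if unique_top and top_n / sum(plain.values()) >= majority:
                out.append(top)
                continue
        out.append(SET_TO_IUPAC[frozenset(observed)])
    return "".join(out)


def species_profile(
    aln: Alignment,
    labels: Mapping[str, str],
    sp: str,
    policy: DistancePolicy = DistancePolicy.STRICT,
    majority: float = 0.5,
    matrix: DistanceMatrix | None = None,
) -> SpeciesProfile:
    """Assemble a species' full characterisation from an alignment.

    ``matrix`` may be supplied to avoid recomputing distances when profiling
    every species of the same alignment.
    """
    m = matrix if matrix is not None else distance_matrix(aln, policy)
    idx = _species_indices(m, labels, sp)
    seqs = [aln[m.ids[i]].sequence for i in idx]
    mi = max_intraspecific(m, labels, sp)
    inter, nearest = min_interspecific(m, labels, sp)
    return SpeciesProfile(
        species=sp,
        n=len(idx),
        max_intra=mi,
        min_inter=inter,
        nearest_species=nearest,
        consensus=consensus_sequence(seqs, majority),
    )


def all_profiles(
    aln: Alignment,
    labels: Mapping[str, str],
    policy: DistancePolicy = DistancePolicy.STRICT,
    majority: float = 0.5,
) -> list[SpeciesProfile]:
    """Profiles for every species in label order of first appearance."""
    m = distance_matrix(aln, policy)
    species: list[str] = []
    for rid in m.ids:
        sp = labels.get(rid)
        if sp is not None and sp not in species:
            species.append(sp)
    return [
        species_profile(aln, labels, sp, policy, majority, matrix=m) for sp in species
    ]


def format_percent(frac: float) -> str:
    """Percent to one decimal, half away from zero; >=10% with .0 collapses to
    an integer (so 0.12 prints as "12", 0.049 as "4.9")."""
    pct = frac * 100.0
    rounded = np.floor(pct * 10 + 0.5) / 10 if pct >= 0 else -np.floor(-pct * 10 + 0.5) / 10
    if rounded >= 10 and rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.1f}"


def characterisation_report(profiles: Sequence[SpeciesProfile]) -> str:
    """Human-readable per-species report, one block per species."""
    if not profiles:
        raise ValueError("no profiles to report")
    blocks = []
    for p in profiles:
        intra = (
            "not applicable" if p.max_intra is None else f"{format_percent(p.max_intra)}%"
        )
        blocks.append(
            f"## {p.species}\n"
            f"Maximum barcode-distance within species: {intra} ({p.n}).\n"
            f"Minimum barcode-distance to closest species: "
            f"{format_percent(p.min_inter)}% ({p.nearest_species}).\n"
            f"Consensus barcode sequence ({len(p.consensus)} bp):\n"
            f"{p.consensus}\n"
        )
    return "\n".join(blocks)


def write_profiles_tsv(profiles: Sequence[SpeciesProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn\tmax_intra_pct\tmin_inter_pct\tnearest\tconsensus\n")
        for p in profiles:
            intra = "NA" if p.max_intra is None else format_percent(p.max_intra)
            fh.write(
                f"{p.species}\t{p.n}\t{intra}\t{format_percent(p.min_inter)}\t"
                f"{p.nearest_species}\t{p.consensus}\n"
            )


def max_intra_from_distance_table(
    path: str | Path, labels: Mapping[str, str], sp: str
) -> tuple[float, int]:
    """Maximum intraspecific distance read from an external labelled matrix.

    Consumes the square percent CSV exported by alignment viewers (header row
    and column of record ids) so published supplementary matrices can be
    re-analysed directly.  Returns ``(fraction, n_records)``.
    """
    from .seqio import read_distance_csv

    m = read_distance_csv(path)
    mi = max_intraspecific(m, labels, sp)
    n = len(_species_indices(m, labels, sp))
    if mi is None:
        raise ValueError(f"species {sp!r} has a single record in {path}")
    return mi, n
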
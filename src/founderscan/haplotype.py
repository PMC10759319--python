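"""Microsatellite haplotype analysis around a disease locus.

Founder alleles descend from one ancestral chromosome, so the carriers'
chromosomes stay identical over a region flanking the locus that shrinks
with each ancestral recombination.  This module phases short-tandem-repeat
genotypes through trios, builds the consensus founder haplotype, and finds
the minimal shared region by marker-by-marker outward extension from the
locus.

Marker genotypes are unordered pairs of allele codes (integer fragment /
repeat lengths as read off capillary electrophoresis); ``None`` marks a
failed genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UNKNOWN",
    "MarkerMap",
    "PhasedChromosome",
    "SharedRegionResult",
    "SharedRegionError",
    "phase_trio",
    "phase_homozygote",
    "consensus_founder_haplotype",
    "CONFLICT",
    "shared_region",
    "read_marker_map",
    "read_marker_genotypes",
    "write_marker_map",
    "write_marker_genotypes",
]

UNKNOWN = None  # per-marker unphased / undetermined state

Genotype = tuple[int, int] | None  # unordered allele pair
SampleGenotypes = dict[str, Genotype]  # marker name -> pair


class SharedRegionError(ValueError):
    """No well-defined shared region around the locus."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered microsatellite markers on one chromosome around a locus.

    ``markers`` is an ordered list of (name, chrom, position_bp) with
    strictly increasing positions; ``locus_position`` must fall strictly
    between two markers, splitting the map into a 5' and a 3' block.
    """

    markers: tuple[tuple[str, str, int], ...]
    locus_position: int

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("need at least two markers")
        chroms = {chrom for _, chrom, _ in self.markers}
        if len(chroms) != 1:
            raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
        positions = [pos for _, _, pos in self.markers]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("marker positions must be strictly increasing")
        names = [name for name, _, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        if not positions[0] < self.locus_position < positions[-1]:
            raise ValueError("locus must lie strictly between the outermost markers")
        if self.locus_position in positions:
            raise ValueError("locus cannot coincide with a marker")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.markers)

    def position(self, name: str) -> int:
        for n, _, pos in self.markers:
            if n == name:
                return pos
        raise KeyError(name)

    @property
    def innermost_5p(self) -> int:
        """Index of the last marker 5' of the locus."""
        return max(
            i for i, (_, _, pos) in enumerate(self.markers)
            if pos < self.locus_position
        )

    @property
    def innermost_3p(self) -> int:
        return self.innermost_5p + 1


@dataclass(frozen=True)
class PhasedChromosome:
    """One chromosome's ordered alleles, as far as Mendelian logic could
    determine them.  ``alleles`` maps marker name -> allele code or
    ``None`` (undetermined)."""

    sample_id: str
    alleles: dict[str, int | None]
    origin: str  # maternal | paternal | homozygote
    mendelian_errors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in ("maternal", "paternal", "homozygote"):
            raise ValueError(f"unknown origin {self.origin!r}")


class _Conflict:
    def __repr__(self) -> str:
        return "CONFLICT"


CONFLICT = _Conflict()  # consensus state where phased chromosomes disagree


@dataclass(frozen=True)
class SharedRegionResult:
    consensus: dict[str, object]  # marker -> allele | None | CONFLICT
    left_marker: str
    right_marker: str
    left_flank: str
    right_flank: str
    span_bp: int  # between outermost shared markers (minimum bound)
    span_bp_max: int  # flank-to-flank (maximum bound)
    n_chromosomes: int
    shared_markers: tuple[str, ...] = ()
    missing_compatible: int = 0  # sharing decisions resting on missing genotypes

    def __post_init__(self) -> None:
        if self.span_bp < 0 or self.span_bp_max < self.span_bp:
            raise ValueError("inconsistent span bounds")


def phase_trio(
    child: SampleGenotypes,
    mother: SampleGenotypes | None,
    father: SampleGenotypes | None,
    carrier_parent: str,
    markers: MarkerMap,
    sample_id: str = "",
) -> PhasedChromosome:
    """Extract the variant-bearing haplotype of a carrier child.

    ``carrier_parent`` ("mother" or "father") names the parent that
    transmitted the disease allele.  At each marker the allele sitting on
    the transmitted chromosome is determined when Mendelian logic is
    unambiguous:

    * child homozygous -> that allele, whatever the parents carry;
    * child heterozygous with exactly one allele present in the
      transmitting parent's genotype (the other therefore attributable
      only to the untransmitting parent) -> that allele;
    * otherwise undetermined.

    A child allele pair impossible given the transmitting parent is a
    Mendelian error: the marker is set undetermined and recorded.
    """
    if carrier_parent not in ("mother", "father"):
        raise ValueError(f"carrier_parent must be mother/father, got {carrier_parent!r}")
    transmitting = mother if carrier_parent == "mother" else father
    origin = "maternal" if carrier_parent == "mother" else "paternal"
    alleles: dict[str, int | None] = {}
    errors: list[str] = []
    for name in markers.names:
        pair = child.get(name)
        if pair is None:
            alleles[name] = None
            continue
        a, b = pair
        if a == b:
            alleles[name] = a
            continue
        t_pair = transmitting.get(name) if transmitting else None
        if t_pair is None:
            alleles[name] = None
            continue
        in_t = [allele for allele in (a, b) if allele in t_pair]
        if len(in_t) == 1:
            alleles[name] = in_t[0]
        elif len(in_t) == 0:
            errors.append(name)
            alleles[name] = None
        else:
            alleles[name] = None  # both alleles possible from this parent
    return PhasedChromosome(
        sample_id=sample_id, alleles=alleles, origin=origin,
        mendelian_errors=tuple(errors),
    )


def phase_homozygote(
    child: SampleGenotypes, markers: MarkerMap, sample_id: str = ""
) -> PhasedChromosome:
    """Haplotype of a proband homozygous for the disease allele: both
    chromosomes carry the founder haplotype, so every marker where the
    proband is homozygous is determined."""
    alleles = {}
    for name in markers.names:
        pair = child.get(name)
        alleles[name] = pair[0] if pair is not None and pair[0] == pair[1] else None
    return PhasedChromosome(sample_id=sample_id, alleles=alleles, origin="homozygote")


def consensus_founder_haplotype(
    phased: list[PhasedChromosome],
) -> dict[str, object]:
    """Per-marker consensus over phased founder chromosomes.

    The unique determined allele when all determined entries agree;
    :data:`CONFLICT` when two determined entries disagree; ``None`` when
    no chromosome is determined at the marker.
    """
    if not phased:
        raise ValueError("need at least one phased chromosome")
    names: list[str] = []
    for chrom in phased:
        for name in chrom.alleles:
            if name not in names:
                names.append(name)
    consensus: dict[str, object] = {}
    for name in names:
        determined = {
            chrom.alleles[name]
            for chrom in phased
            if chrom.alleles.get(name) is not None
        }
        if not determined:
            consensus[name] = None
        elif len(determined) == 1:
            consensus[name] = determined.pop()
        else:
            consensus[name] = CONFLICT
    return consensus


def shared_region(
    consensus: dict[str, object],
    carriers: dict[str, SampleGenotypes],
    marker_map: MarkerMap,
    require_homozygous: bool = False,
) -> SharedRegionResult:
    """Minimal region over which all carrier chromosomes share the
    founder haplotype.

    Starting at the innermost 5' and 3' markers and extending outward
    one marker at a time, a marker is *shared* iff the consensus is
    determined there and every carrier's genotype pair contains the
    consensus allele (a missing genotype cannot contradict sharing and
    counts as compatible; ``require_homozygous`` demands homozygosity
    for the consensus allele instead).  Extension stops at the first
    non-shared marker on each side.

    The span between the outermost shared markers is the minimum bound
    on the conserved region; flank-to-flank is the maximum bound.
    """
    names = marker_map.names
    i5, i3 = marker_map.innermost_5p, marker_map.innermost_3p
    missing_used = 0

    def status(idx: int) -> str:
        nonlocal missing_used
        allele = consensus.get(names[idx])
        if allele is CONFLICT:
            return "conflict"
        if allele is None:
            return "unshared"
        local_missing = 0
        for genotypes in carriers.values():
            pair = genotypes.get(names[idx])
            if pair is None:
                local_missing += 1
                continue
            if require_homozygous:
                if not (pair[0] == allele and pair[1] == allele):
                    return "unshared"
            elif allele not in pair:
                return "unshared"
        missing_used += local_missing
        return "shared"

    for idx in (i5, i3):
        st = status(idx)
        if st == "conflict":
            raise SharedRegionError(
                f"consensus conflict at innermost marker {names[idx]}"
            )
        if st == "unshared":
            raise SharedRegionError(
                f"no sharing at innermost marker {names[idx]}"
            )

    left = i5
    while left - 1 >= 0 and status(left - 1) == "shared":
        left -= 1
    right = i3
    while right + 1 < len(names) and status(right + 1) == "shared":
        right += 1

    left_flank = max(left - 1, 0)
    right_flank = min(right + 1, len(names) - 1)
    shared = tuple(names[left:right + 1])
    pos = {name: p for name, _, p in marker_map.markers}
    return SharedRegionResult(
        consensus=dict(consensus),
        left_marker=names[left],
        right_marker=names[right],
        left_flank=names[left_flank],
        right_flank=names[right_flank],
        span_bp=pos[names[right]] - pos[names[left]],
        span_bp_max=pos[names[right_flank]] - pos[names[left_flank]],
        n_chromosomes=len(carriers),
        shared_markers=shared,
        missing_compatible=missing_used,
    )


# ---------------------------------------------------------------------------
# file formats

def read_marker_map(
    path, locus_position: int | None = None
) -> MarkerMap:
    """Marker map TSV: name, chrom, position_bp, side (5p|3p).

    When ``locus_position`` is omitted it is placed midway between the
    innermost 5' and 3' markers as labeled by the side column.
    """
    rows: list[tuple[str, str, int, str]] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        need = ["name", "chrom", "position_bp", "side"]
        if header != need:
            raise ValueError(f"{path}: expected columns {need}")
        for line in fh:
            if not line.strip():
                continue
            name, chrom, pos, side = line.rstrip("\n").split("\t")
            if side not in ("5p", "3p"):
                raise ValueError(f"{path}: side must be 5p/3p, got {side!r}")
            rows.append((name, chrom, int(pos), side))
    rows.sort(key=lambda r: r[2])
    if locus_position is None:
        five = [pos for _, _, pos, side in rows if side == "5p"]
        three = [pos for _, _, pos, side in rows if side == "3p"]
        if not five or not three:
            raise ValueError(f"{path}: need markers on both sides of the locus")
        locus_position = (max(five) + min(three)) // 2
    return MarkerMap(
        markers=tuple((name, chrom, pos) for name, chrom, pos, _ in rows),
        locus_position=locus_position,
    )


def write_marker_map(path, marker_map: MarkerMap) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tposition_bp\tside\n")
        for name, chrom, pos in marker_map.markers:
            side = "5p" if pos < marker_map.locus_position else "3p"
            fh.write(f"{name}\t{chrom}\t{pos}\t{side}\n")


def read_marker_genotypes(path) -> dict[str, SampleGenotypes]:
    """Genotype TSV: sample_id, marker, allele1, allele2 ('.' = missing)."""
    out: dict[str, SampleGenotypes] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        need = ["sample_id", "marker", "allele1", "allele2"]
        if header != need:
            raise ValueError(f"{path}: expected columns {need}")
        for line in fh:
            if not line.strip():
                continue
            sid, marker, a1, a2 = line.rstrip("\n").split("\t")
            genotypes = out.setdefault(sid, {})
            if a1 == "." or a2 == ".":
                genotypes[marker] = None
            else:
                genotypes[marker] = (int(a1), int(a2))
    return out


def write_marker_genotypes(path, genotypes: dict[str, SampleGenotypes]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmarker\tallele1\tallele2\n")
        for sid, sample in genotypes.items():
            for marker, pair in sample.items():
                if pair is None:
                    fh.write(f"{sid}\t{marker}\t.\t.\n")
                else:
                    fh.write(f"{sid}\t{marker}\t{pair[0]}\t{pair[1]}\n")
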
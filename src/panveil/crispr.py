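"""CRISPR repeat–spacer array detection in nucleotide genomes.

The detector follows the CRT/CRISPRCasFinder family of algorithms: exact
k-mer seeding of candidate repeat pairs, maximal extension of the repeat
unit, and an outward walk collecting repeat–spacer units while length and
identity constraints hold.  Two conventions come from the study design this
package reproduces: flanking regions of up to 100 bp are attached to every
reported array, and a terminal *truncated* repeat (a partial unit at least
half the repeat length, matching the consensus prefix or suffix) is kept
and flagged rather than discarded.

Coordinates are 0-based half-open throughout; the GFF3 writer converts to
1-based inclusive.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

DNA = "ACGT"


@dataclass(frozen=True)
class CrisprParams:
    """Detection constraints.

    Defaults follow common CRT/CRISPRCasFinder practice: direct repeats of
    23–55 bp, spacers between 0.5× and 2.5× the repeat length, at least
    3 repeat units (2 behind the permissive flag), and ≥0.8 identity of
    each full repeat instance to the array consensus.
    """

    min_repeat: int = 23
    max_repeat: int = 55
    min_spacer_ratio: float = 0.5
    max_spacer_ratio: float = 2.5
    min_units: int = 3
    min_identity: float = 0.8
    # a truncated terminal unit carries fewer informative bases than a full
    # unit, so it must clear a stricter identity bar to count as evidence
    truncated_min_identity: float = 0.9
    seed_k: int = 8
    flank_size: int = 100
    permissive_two_units: bool = False

    @property
    def effective_min_units(self) -> int:
        return 2 if self.permissive_two_units else self.min_units

    def seed_window(self) -> tuple[int, int]:
        """Distance window between recurring k-mers that can anchor an array.

        Two copies of a k-mer sitting at the same offset of consecutive
        repeat units are one period (repeat + spacer) apart, hence at least
        ``k + min_spacer`` and at most ``k + max_spacer + max_repeat``.
        """
        lo = self.seed_k + math.ceil(self.min_spacer_ratio * self.min_repeat)
        hi = self.seed_k + math.floor(self.max_spacer_ratio * self.max_repeat) + self.max_repeat
        return lo, hi


@dataclass
class CrisprArray:
    """One detected (or planted) repeat–spacer array.

    ``repeat_instances`` and ``spacers`` alternate and tile
    ``[start, end)`` without overlap; the number of repeat instances is
    always one more than the number of spacers.
    """

    genome_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_instances: list[tuple[int, int, bool]] = field(default_factory=list)
    spacers: list[tuple[int, int]] = field(default_factory=list)
    left_flank: str = ""
    right_flank: str = ""

    @property
    def n_units(self) -> int:
        return len(self.repeat_instances)

    @property
    def has_truncated_unit(self) -> bool:
        return any(t for _, _, t in self.repeat_instances)

    @property
    def repeat_length(self) -> int:
        return len(self.repeat_consensus)

    def validate(self, genome: str | None = None) -> None:
        """Check the tiling/alternation invariants; raise ValueError on violation."""
        if len(self.repeat_instances) != len(self.spacers) + 1:
            raise ValueError("n_repeats must equal n_spacers + 1")
        segments = []
        for i, (s, e, _) in enumerate(self.repeat_instances):
            segments.append((s, e))
            if i < len(self.spacers):
                segments.append(self.spacers[i])
        if segments[0][0] != self.start or segments[-1][1] != self.end:
            raise ValueError("units do not span [start, end)")
        for (a, b), (c, _) in zip(segments, segments[1:]):
            if b != c or a >= b:
                raise ValueError("units must tile the array without gaps or overlap")
        if genome is not None:
            if self.left_flank != genome[max(0, self.start - len(self.left_flank)) : self.start]:
                raise ValueError("left flank does not match genome")
            if self.right_flank != genome[self.end : self.end + len(self.right_flank)]:
                raise ValueError("right flank does not match genome")


@dataclass(frozen=True)
class Rejection:
    """Why a candidate seed did not validate into an array."""

    reason: str
    seed: tuple[int, int]


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_repeat_seeds(genome: str, k: int = 8, window: tuple[int, int] | None = None) -> list[tuple[int, int]]:
    """Positions of exact k-mer pairs recurring within the period window.

    Returns (p1, p2) anchor pairs with ``window[0] <= p2 - p1 <= window[1]``.
    k-mers containing any non-ACGT character (e.g. N) never match.
    """
    if window is None:
        window = CrisprParams(seed_k=k).seed_window()
    lo, hi = window
    occurrences: dict[str, list[int]] = defaultdict(list)
    n = len(genome)
    seeds: list[tuple[int, int]] = []
    for i in range(n - k + 1):
        kmer = genome[i : i + k]
        if any(c not in DNA for c in kmer):
            continue
        for p in reversed(occurrences[kmer]):
            d = i - p
            if d > hi:
                break
            if d >= lo:
                seeds.append((p, i))
        occurrences[kmer].append(i)
    seeds.sort()
    return seeds


def _best_unit_in_window(genome: str, q0: int, q1: int, length: int, template: str, min_identity: float) -> tuple[int, float] | None:
    """Best-identity full-unit match with start in [q0, q1]; earliest on ties."""
    best: tuple[int, float] | None = None
    for q in range(max(0, q0), q1 + 1):
        if q + length > len(genome):
            break
        ident = _identity(genome[q : q + length], template)
        if ident >= min_identity and (best is None or ident > best[1]):
            best = (q, ident)
    return best


def _terminal_truncated_right(genome: str, q0: int, q1: int, consensus: str, params: CrisprParams) -> tuple[int, int] | None:
    """Partial unit matching the consensus *prefix*, at least half length."""
    r = len(consensus)
    best: tuple[float, int, int] | None = None  # (identity, t, q)
    for q in range(max(0, q0), min(q1, len(genome) - 1) + 1):
        for t in range(r // 2, r):
            if q + t > len(genome):
                break
            ident = _identity(genome[q : q + t], consensus[:t])
            if ident >= params.truncated_min_identity and (best is None or (ident, t) > (best[0], best[1])):
                best = (ident, t, q)
    if best is None:
        return None
    return best[2], best[2] + best[1]


def _terminal_truncated_left(genome: str, e0: int, e1: int, consensus: str, params: CrisprParams) -> tuple[int, int] | None:
    """Partial unit matching the consensus *suffix*, ending in [e0, e1]."""
    r = len(consensus)
    best: tuple[float, int, int] | None = None
    for e in range(min(e1, len(genome)), max(e0, 0) - 1, -1):
        for t in range(r // 2, r):
            if e - t < 0:
                break
            ident = _identity(genome[e - t : e], consensus[r - t :])
            if ident >= params.truncated_min_identity and (best is None or (ident, t) > (best[0], best[1])):
                best = (ident, t, e)
    if best is None:
        return None
    return best[2] - best[1], best[2]


def extend_and_validate(genome: str, seed: tuple[int, int], params: CrisprParams | None = None, genome_id: str = "genome"):
    """Grow a seeded repeat pair into a full array, or reject it.

    Returns a :class:`CrisprArray` on success, else a :class:`Rejection`
    carrying a reason code.
    """
    if params is None:
        params = CrisprParams()
    p1, p2 = seed
    d = p2 - p1
    n = len(genome)

    # Maximal exact extension of the matching pair; the unit may not absorb
    # the whole period (a spacer must remain).
    left = 0
    while p1 - 1 - left >= 0 and genome[p1 - 1 - left] == genome[p2 - 1 - left]:
        left += 1
    right = 0
    while p2 + right < n and left + right < d and genome[p1 + right] == genome[p2 + right]:
        right += 1
    repeat_len = left + right
    if repeat_len < params.min_repeat:
        return Rejection("repeat_too_short", seed)
    if repeat_len > params.max_repeat:
        return Rejection("repeat_too_long", seed)
    spacer0 = d - repeat_len
    min_sp = math.ceil(params.min_spacer_ratio * repeat_len)
    max_sp = math.floor(params.max_spacer_ratio * repeat_len)
    if not (min_sp <= spacer0 <= max_sp):
        return Rejection("spacer_out_of_bounds", seed)

    unit0 = genome[p1 - left : p1 - left + repeat_len]
    starts = [p1 - left, p2 - left]

    # Walk right, then left, collecting full units while a window around the
    # expected spacer distance still contains a match.
    while True:
        last = starts[-1]
        found = _best_unit_in_window(
            genome, last + repeat_len + min_sp, last + repeat_len + max_sp, repeat_len, unit0, params.min_identity
        )
        if found is None:
            break
        starts.append(found[0])
    while True:
        first = starts[0]
        found = _best_unit_in_window(
            genome, first - max_sp - repeat_len, first - min_sp - repeat_len, repeat_len, unit0, params.min_identity
        )
        if found is None or found[0] + repeat_len + min_sp > first:
            break
        starts.insert(0, found[0])

    # Boundary refinement: the pairwise seed extension can overshoot by a
    # base or two when flanking bases of the seeded pair match by chance;
    # trim terminal columns that are not conserved across *all* full units.
    def _modal_freq(col: list[str]) -> float:
        return max(col.count(c) for c in set(col)) / len(col)

    while repeat_len > params.min_repeat:
        if _modal_freq([genome[s] for s in starts]) >= params.min_identity:
            break
        starts = [s + 1 for s in starts]
        repeat_len -= 1
    while repeat_len > params.min_repeat:
        if _modal_freq([genome[s + repeat_len - 1] for s in starts]) >= params.min_identity:
            break
        repeat_len -= 1
    min_sp = math.ceil(params.min_spacer_ratio * repeat_len)
    max_sp = math.floor(params.max_spacer_ratio * repeat_len)
    for a_start, b_start in zip(starts, starts[1:]):
        if not (min_sp <= b_start - (a_start + repeat_len) <= max_sp):
            return Rejection("spacer_out_of_bounds", seed)

    # Consensus = columnwise modal base over full units (lexicographic ties).
    columns = [[genome[s + i] for s in starts] for i in range(repeat_len)]
    consensus = "".join(max(sorted(set(col)), key=col.count) for col in columns)
    if any(_identity(genome[s : s + repeat_len], consensus) < params.min_identity for s in starts):
        return Rejection("unit_below_identity", seed)

    instances: list[tuple[int, int, bool]] = [(s, s + repeat_len, False) for s in starts]
    trunc = _terminal_truncated_right(
        genome, starts[-1] + repeat_len + min_sp, starts[-1] + repeat_len + max_sp, consensus, params
    )
    if trunc is not None:
        instances.append((trunc[0], trunc[1], True))
    # a left-truncated unit ends one spacer before the first full unit
    trunc_l = _terminal_truncated_left(genome, starts[0] - max_sp, starts[0] - min_sp, consensus, params)
    if trunc_l is not None and trunc_l[0] >= 0:
        instances.insert(0, (trunc_l[0], trunc_l[1], True))

    if len(instances) < params.effective_min_units:
        return Rejection("too_few_units", seed)

    spacers = [(a_end, b_start) for (_, a_end, _), (b_start, _, _) in zip(instances, instances[1:])]
    start, end = instances[0][0], instances[-1][1]
    array = CrisprArray(
        genome_id=genome_id,
        start=start,
        end=end,
        repeat_consensus=consensus,
        repeat_instances=instances,
        spacers=spacers,
        left_flank=genome[max(0, start - params.flank_size) : start],
        right_flank=genome[end : end + params.flank_size],
    )
    array.validate(genome)
    return array


def scan_genome(genome: str, params: CrisprParams | None = None, genome_id: str = "genome") -> list[CrisprArray]:
    """All non-overlapping accepted arrays, in coordinate order.

    Candidates from every seed are deduplicated by span; overlaps are
    resolved greedily by descending unit count, then leftmost start.
    Deterministic for a given genome.
    """
    if params is None:
        params = CrisprParams()
    genome = genome.upper()
    lo, hi = params.seed_window()
    candidates: dict[tuple[int, int], CrisprArray] = {}
    for seed in find_repeat_seeds(genome, k=params.seed_k, window=(lo, hi)):
        result = extend_and_validate(genome, seed, params, genome_id=genome_id)
        if isinstance(result, CrisprArray):
            candidates.setdefault((result.start, result.end), result)
    ordered = sorted(candidates.values(), key=lambda a: (-a.n_units, a.start))
    chosen: list[CrisprArray] = []
    for arr in ordered:
        if all(arr.end <= c.start or arr.start >= c.end for c in chosen):
            chosen.append(arr)
    return sorted(chosen, key=lambda a: a.start)


# ---------------------------------------------------------------------------
# serialisation

def write_arrays_tsv(arrays: list[CrisprArray], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tstart\tend\tn_repeats\trepeat_len\tconsensus\ttruncated\n")
        for a in arrays:
            fh.write(
                f"{a.genome_id}\t{a.start}\t{a.end}\t{a.n_units}\t{a.repeat_length}\t"
                f"{a.repeat_consensus}\t{int(a.has_truncated_unit)}\n"
            )


def write_arrays_gff3(arrays: list[CrisprArray], path) -> None:
    """GFF3 export: `repeat_region` parents with direct_repeat/spacer children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(arrays, 1):
            rid = f"crispr{i}"
            fh.write(
                f"{a.genome_id}\tpanveil\trepeat_region\t{a.start + 1}\t{a.end}\t.\t+\t.\t"
                f"ID={rid};n_repeats={a.n_units};repeat_consensus={a.repeat_consensus}\n"
            )
            for j, (s, e, tr) in enumerate(a.repeat_instances, 1):
                attr = f"ID={rid}.DR{j};Parent={rid}" + (";truncated=true" if tr else "")
                fh.write(f"{a.genome_id}\tpanveil\tdirect_repeat\t{s + 1}\t{e}\t.\t+\t.\t{attr}\n")
            for j, (s, e) in enumerate(a.spacers, 1):
                fh.write(f"{a.genome_id}\tpanveil\tspacer\t{s + 1}\t{e}\t.\t+\t.\tID={rid}.SP{j};Parent={rid}\n")


def write_flanks_fasta(arrays: list[CrisprArray], path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(arrays, 1):
            if a.left_flank:
                fh.write(f">{a.genome_id}|crispr{i}|left_flank\n{a.left_flank}\n")
            if a.right_flank:
                fh.write(f">{a.genome_id}|crispr{i}|right_flank\n{a.right_flank}\n")
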
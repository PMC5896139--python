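"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as direct predicate enumeration over substrings or
candidate windows — deliberately naive, sharing no code with the package.
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# island scanner oracle: O(n^2) candidate enumeration + greedy dedup walk


def brute_force_scan(records, chrom_length, config, sequence=None):
    """Enumerate every (first-SNP, last-SNP) candidate core satisfying the
    island predicates, then walk left to right emitting the leftmost-anchor,
    earliest-completing candidate, exactly once per anchor attempt.

    Returns a list of (core_start, core_end, impactful_positions,
    relevant_positions) tuples.
    """

    def klass(af):
        if config.impactful_lo <= af <= config.impactful_hi:
            return "I"
        if af <= config.conserved_max_af or af >= config.conserved_min_af_hi:
            return "-"
        return "R"

    events = [(r.pos, klass(r.af)) for r in records if klass(r.af) != "-"]

    def clean(lo, hi):
        if lo < 1 or hi > chrom_length:
            return False
        if any(lo <= pos <= hi for pos, _ in events):
            return False
        if sequence is not None and "N" in sequence[lo - 1 : hi]:
            return False
        return True

    flank = config.min_flank_len
    n = len(events)

    def candidate_end(a):
        """Earliest event index j completing an island anchored at events[a]."""
        if events[a][1] != "I" or not clean(events[a][0] - flank, events[a][0] - 1):
            return None
        count = 0
        for j in range(a, n):
            pos_j, cls_j = events[j]
            if pos_j - events[a][0] + 1 > config.max_island_len:
                return None
            count += cls_j == "I"
            if count >= config.min_impactful and clean(pos_j + 1, pos_j + flank):
                return j
        return None

    islands = []
    a = 0
    while a < n:
        j = candidate_end(a)
        if j is None:
            a += 1
            continue
        members = events[a : j + 1]
        islands.append(
            (
                events[a][0],
                events[j][0],
                tuple(p for p, c in members if c == "I"),
                tuple(p for p, c in members if c == "R"),
            )
        )
        a = j + 1
    return islands


# ---------------------------------------------------------------------------
# sequence-filter oracles: per-window / per-start direct string comparison


def window_homopolymer_reject(sequence, window_len=20, min_run=4, total=10):
    """Check every window substring by literal run counting."""
    n = len(sequence)
    if n <= window_len:
        windows = [sequence]
    else:
        windows = [sequence[i : i + window_len] for i in range(n - window_len + 1)]
    for win in windows:
        for base in "ACGT":
            run_sum = 0
            run = 0
            for ch in win + "$":
                if ch == base:
                    run += 1
                else:
                    if run >= min_run:
                        run_sum += run
                    run = 0
            if run_sum >= total:
                return True
    return False


def _is_primitive(unit):
    return (unit + unit).find(unit, 1) == len(unit)


def direct_tandem_reject(sequence, unit_min=2, unit_max=7, max_rep=5):
    """Try every start and unit length by literal unit multiplication."""
    n = len(sequence)
    for u in range(unit_min, unit_max + 1):
        for i in range(n - u * (max_rep + 1) + 1):
            unit = sequence[i : i + u]
            if "N" in unit or not _is_primitive(unit):
                continue
            if sequence[i : i + u * (max_rep + 1)] == unit * (max_rep + 1):
                return True
    return False


# ---------------------------------------------------------------------------
# uniqueness oracle: forward-strand substring tally + explicit RC lookup


def substring_unique_positions(flank_seq, genome_sequences, k):
    """Anchored flags per flank start, from a plain forward k-mer tally."""
    comp = str.maketrans("ACGTN", "TGCAN")
    fwd = {}
    for seq in genome_sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= set("ACGT"):
                fwd[kmer] = fwd.get(kmer, 0) + 1
    flags = []
    for i in range(len(flank_seq) - k + 1):
        kmer = flank_seq[i : i + k]
        if not set(kmer) <= set("ACGT"):
            flags.append(False)
            continue
        rc = kmer.translate(comp)[::-1]
        count = fwd.get(kmer, 0)
        if rc != kmer:
            count += fwd.get(rc, 0)
        flags.append(count == 1)
    return flags


def stretches_from_flags(flags, k, min_len):
    """(start_offset, length) of maximal anchored runs strictly longer than
    min_len, offsets 0-based into the flank."""
    out = []
    i = 0
    while i < len(flags):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flags) and flags[j + 1]:
            j += 1
        length = j - i + k
        if length > min_len:
            out.append((i, length))
        i = j + 1
    return out
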
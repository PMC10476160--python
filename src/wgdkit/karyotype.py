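"""Telomere-centric karyotype event engine.

A karyotype is an ordered list of chromosomes, each an ordered list of
oriented segments labelled by their ancestral chromosome of origin (spans
are fractions of the ancestral chromosome, half-open in [0, 1)).  Six event
kinds rewrite it:

=====  ===========================================================  =========
kind   effect                                                       count
=====  ===========================================================  =========
EEJ    end-to-end joining of two chromosomes                        -1
NCF    nested fusion: donor inserted into the host                  -1
XO     crossover: reciprocal exchange of distal chromosome arms      0
IV     segmental inversion inside one chromosome                     0
WGD    whole-genome duplication (copy suffixes a/b)                 x2
WGT    whole-genome triplication (suffixes a/b/c)                   x3
=====  ===========================================================  =========

Every EEJ or NCF records one satellite remnant from the two telomeres it
joins; satellites never re-enter the karyotype and are excluded from
chromosome counts, consistent with their frequent loss during evolution.

Event scripts are plain text, one event per line::

    EEJ chr3 chr7
    NCF host=chr2 donor=chr5 pos=0.5
    XO chr1@0.4 chr6@0.7
    IV chr4@0.2-0.6
    WGD
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ValidationError, read_tsv, write_tsv

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """A run of one ancestral chromosome: label, span in [0,1), orientation."""

    ancestral_chrom: str
    lo: float
    hi: float
    orientation: int = 1

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(
                f"empty segment span [{self.lo}, {self.hi}) on {self.ancestral_chrom}"
            )
        if self.orientation not in (1, -1):
            raise ValidationError("orientation must be +1 or -1")

    @property
    def length(self) -> float:
        return self.hi - self.lo

    def reversed_(self) -> "Segment":
        return Segment(self.ancestral_chrom, self.lo, self.hi, -self.orientation)


@dataclass
class Chromosome:
    name: str
    segments: list[Segment]

    @property
    def length(self) -> float:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class Satellite:
    label: str
    telomere_a: str  # "<chrom>:<end>" descriptors of the joined telomeres
    telomere_b: str


@dataclass(frozen=True)
class KaryoEvent:
    kind: str  # EEJ | NCF | XO | IV | WGD | WGT
    operands: tuple = ()
    params: dict = field(default_factory=dict)


@dataclass
class Karyotype:
    """Ordered chromosomes plus the satellite ledger and event history."""

    chromosomes: list[Chromosome]
    satellites: list[Satellite] = field(default_factory=list)
    history: list[str] = field(default_factory=list)
    generation_tag: str = ""

    @classmethod
    def from_labels(cls, labels: Iterable[str], tag: str = "") -> "Karyotype":
        """One single-segment chromosome per ancestral label."""
        return cls(
            chromosomes=[
                Chromosome(name=l, segments=[Segment(l, 0.0, 1.0, 1)]) for l in labels
            ],
            generation_tag=tag,
        )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ValidationError(f"no chromosome named {name!r}")

    def copy(self) -> "Karyotype":
        return Karyotype(
            chromosomes=[Chromosome(c.name, list(c.segments)) for c in self.chromosomes],
            satellites=list(self.satellites),
            history=list(self.history),
            generation_tag=self.generation_tag,
        )

    def ancestral_length(self) -> dict[str, float]:
        """Total span length carried per ancestral chromosome."""
        out: dict[str, float] = {}
        for c in self.chromosomes:
            for s in c.segments:
                out[s.ancestral_chrom] = out.get(s.ancestral_chrom, 0.0) + s.length
        return out


def _split_at_length(segments: Sequence[Segment], target: float) -> tuple[list[Segment], list[Segment]]:
    """Split a segment list at a traversal distance from its left end."""
    left: list[Segment] = []
    acc = 0.0
    for i, s in enumerate(segments):
        if abs(acc - target) < _EPS:
            return left, list(segments[i:])
        if acc + s.length <= target + _EPS:
            left.append(s)
            acc += s.length
            continue
        t = target - acc
        if s.orientation > 0:
            left.append(Segment(s.ancestral_chrom, s.lo, s.lo + t, 1))
            right_first = Segment(s.ancestral_chrom, s.lo + t, s.hi, 1)
        else:
            left.append(Segment(s.ancestral_chrom, s.hi - t, s.hi, -1))
            right_first = Segment(s.ancestral_chrom, s.lo, s.hi - t, -1)
        return left, [right_first, *segments[i + 1 :]]
    return left, []


def _split_at_fraction(chrom: Chromosome, frac: float) -> tuple[list[Segment], list[Segment]]:
    if not 0.0 < frac < 1.0:
        raise ValidationError(
            f"breakpoint fraction must be strictly inside (0,1), got {frac}"
        )
    return _split_at_length(chrom.segments, frac * chrom.length)


def normalize(segments: Sequence[Segment]) -> list[Segment]:
    """Merge adjacent segments that are contiguous on the same ancestor."""
    out: list[Segment] = []
    for s in segments:
        if out:
            p = out[-1]
            if (
                p.ancestral_chrom == s.ancestral_chrom
                and p.orientation == s.orientation
            ):
                if p.orientation > 0 and abs(p.hi - s.lo) < _EPS:
                    out[-1] = Segment(p.ancestral_chrom, p.lo, s.hi, 1)
                    continue
                if p.orientation < 0 and abs(p.lo - s.hi) < _EPS:
                    out[-1] = Segment(p.ancestral_chrom, s.lo, p.hi, -1)
                    continue
        out.append(s)
    return out


def _telomere(chrom: Chromosome, end: str) -> str:
    seg = chrom.segments[0] if end == "start" else chrom.segments[-1]
    return f"{chrom.name}:{end}:{seg.ancestral_chrom}"


def apply_event(karyotype: Karyotype, event: KaryoEvent) -> Karyotype:
    """Apply one event, returning a new karyotype (the input is untouched)."""
    k = karyotype.copy()
    kind = event.kind
    if kind == "EEJ":
        name_a, name_b = event.operands
        if name_a == name_b:
            raise ValidationError("EEJ requires two distinct chromosomes")
        a, b = k.get(name_a), k.get(name_b)
        sat = Satellite(
            label=f"S{len(k.satellites) + 1}",
            telomere_a=_telomere(a, "end"),
            telomere_b=_telomere(b, "start"),
        )
        a.segments = normalize([*a.segments, *b.segments])
        k.chromosomes.remove(b)
        k.satellites.append(sat)
    elif kind == "NCF":
        host_name, donor_name = event.operands
        if host_name == donor_name:
            raise ValidationError("NCF requires two distinct chromosomes")
        pos = float(event.params.get("pos", 0.5))  # centromere proxy
        host, donor = k.get(host_name), k.get(donor_name)
        left, right = _split_at_fraction(host, pos)
        sat = Satellite(
            label=f"S{len(k.satellites) + 1}",
            telomere_a=_telomere(donor, "start"),
            telomere_b=_telomere(donor, "end"),
        )
        host.segments = normalize([*left, *donor.segments, *right])
        k.chromosomes.remove(donor)
        k.satellites.append(sat)
    elif kind == "XO":
        name_a, name_b = event.operands
        if name_a == name_b:
            raise ValidationError("XO requires two distinct chromosomes")
        fa = float(event.params["pos_a"])
        fb = float(event.params["pos_b"])
        a, b = k.get(name_a), k.get(name_b)
        head_a, tail_a = _split_at_fraction(a, fa)
        head_b, tail_b = _split_at_fraction(b, fb)
        a.segments = normalize([*head_a, *tail_b])
        b.segments = normalize([*head_b, *tail_a])
    elif kind == "IV":
        (name,) = event.operands
        f1 = float(event.params["lo"])
        f2 = float(event.params["hi"])
        if not 0.0 <= f1 < f2 <= 1.0:
            raise ValidationError(f"inversion interval [{f1}, {f2}] is invalid")
        c = k.get(name)
        total = c.length
        head, rest = _split_at_length(c.segments, f1 * total)
        mid, tail = _split_at_length(rest, (f2 - f1) * total)
        inverted = [s.reversed_() for s in reversed(mid)]
        c.segments = normalize([*head, *inverted, *tail])
    elif kind in ("WGD", "WGT"):
        suffixes = "ab" if kind == "WGD" else "abc"
        k.chromosomes = [
            Chromosome(name=f"{c.name}{suffix}", segments=list(c.segments))
            for c in k.chromosomes
            for suffix in suffixes
        ]
    else:
        raise ValidationError(f"unknown event kind {kind!r}")
    k.history.append(kind)
    return k


def run_script(
    karyotype: Karyotype, events: Sequence[KaryoEvent]
) -> tuple[Karyotype, list[tuple[int, str, int]]]:
    """Apply events in order; log (step, kind, chromosome count) per step.

    The first invalid step aborts with its index in the error message.
    """
    log: list[tuple[int, str, int]] = []
    k = karyotype
    for step, event in enumerate(events, 1):
        try:
            k = apply_event(k, event)
        except ValidationError as exc:
            raise ValidationError(f"script step {step} ({event.kind}): {exc}") from exc
        log.append((step, event.kind, k.n_chromosomes))
    return k, log


_XO_OPERAND = re.compile(r"^(?P<name>.+)@(?P<pos>[0-9.]+)$")
_IV_OPERAND = re.compile(r"^(?P<name>.+)@(?P<lo>[0-9.]+)-(?P<hi>[0-9.]+)$")


def parse_event(line: str) -> KaryoEvent:
    tokens = line.split()
    kind = tokens[0].upper()
    if kind in ("WGD", "WGT"):
        if len(tokens) != 1:
            raise ValidationError(f"{kind} takes no operands: {line!r}")
        return KaryoEvent(kind=kind)
    if kind == "EEJ":
        if len(tokens) != 3:
            raise ValidationError(f"EEJ takes two chromosome names: {line!r}")
        return KaryoEvent(kind="EEJ", operands=(tokens[1], tokens[2]))
    if kind == "NCF":
        params = dict(t.split("=", 1) for t in tokens[1:] if "=" in t)
        if "host" not in params or "donor" not in params:
            raise ValidationError(f"NCF needs host= and donor=: {line!r}")
        ev_params = {}
        if "pos" in params:
            ev_params["pos"] = float(params["pos"])
        return KaryoEvent(
            kind="NCF", operands=(params["host"], params["donor"]), params=ev_params
        )
    if kind == "XO":
        if len(tokens) != 3:
            raise ValidationError(f"XO takes two chrom@pos operands: {line!r}")
        ma, mb = _XO_OPERAND.match(tokens[1]), _XO_OPERAND.match(tokens[2])
        if not ma or not mb:
            raise ValidationError(f"XO operand must be chrom@pos: {line!r}")
        return KaryoEvent(
            kind="XO",
            operands=(ma["name"], mb["name"]),
            params={"pos_a": float(ma["pos"]), "pos_b": float(mb["pos"])},
        )
    if kind == "IV":
        if len(tokens) != 2:
            raise ValidationError(f"IV takes one chrom@lo-hi operand: {line!r}")
        m = _IV_OPERAND.match(tokens[1])
        if not m:
            raise ValidationError(f"IV operand must be chrom@lo-hi: {line!r}")
        return KaryoEvent(
            kind="IV",
            operands=(m["name"],),
            params={"lo": float(m["lo"]), "hi": float(m["hi"])},
        )
    raise ValidationError(f"unknown event kind {kind!r}")


def parse_script(text: str) -> list[KaryoEvent]:
    events = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            events.append(parse_event(line))
        except ValidationError as exc:
            raise ValidationError(f"event script line {lineno}: {exc}") from exc
    return events


def expected_dotplot(
    k1: Karyotype, k2: Karyotype
) -> list[tuple[str, tuple[float, float], str, tuple[float, float], int]]:
    """Predicted homologous tracts between two karyotypes.

    For every pair of segments sharing an ancestral chromosome with
    overlapping spans, reports (chrom1, local interval on chrom1, chrom2,
    local interval on chrom2, orientation product); local intervals are
    traversal fractions of the chromosome.  An empty ancestral-label overlap
    yields an empty list.
    """
    tracts = []
    for c1 in k1.chromosomes:
        off1 = 0.0
        for s1 in c1.segments:
            for c2 in k2.chromosomes:
                off2 = 0.0
                for s2 in c2.segments:
                    if s1.ancestral_chrom == s2.ancestral_chrom:
                        lo = max(s1.lo, s2.lo)
                        hi = min(s1.hi, s2.hi)
                        if hi - lo > _EPS:
                            tracts.append(
                                (
                                    c1.name,
                                    _local_interval(s1, off1, c1.length, lo, hi),
                                    c2.name,
                                    _local_interval(s2, off2, c2.length, lo, hi),
                                    s1.orientation * s2.orientation,
                                )
                            )
                    off2 += s2.length
            off1 += s1.length
    return tracts


def _local_interval(
    seg: Segment, offset: float, chrom_len: float, lo: float, hi: float
) -> tuple[float, float]:
    if seg.orientation > 0:
        a, b = offset + (lo - seg.lo), offset + (hi - seg.lo)
    else:
        a, b = offset + (seg.hi - hi), offset + (seg.hi - lo)
    return (a / chrom_len, b / chrom_len)


@dataclass(frozen=True)
class AdjacencyCall:
    """Fusion-timing classification of one ancestral-chromosome junction."""

    chrom_a: str
    coord_a: float
    chrom_b: str
    coord_b: float
    copies: int
    timing: str  # pre_wgd | post_wgd | ambiguous


def _junctions(k: Karyotype) -> list[tuple[tuple[str, float], tuple[str, float]]]:
    out = []
    for c in k.chromosomes:
        segs = normalize(c.segments)
        for s1, s2 in zip(segs, segs[1:]):
            if s1.ancestral_chrom == s2.ancestral_chrom:
                continue
            end1 = s1.hi if s1.orientation > 0 else s1.lo
            start2 = s2.lo if s2.orientation > 0 else s2.hi
            out.append(
                ((s1.ancestral_chrom, round(end1, 9)), (s2.ancestral_chrom, round(start2, 9)))
            )
    return out


def infer_fusion_timing(
    post_wgd: Karyotype, ancestor: Karyotype
) -> list[AdjacencyCall]:
    """Classify each fusion junction as pre- or post-WGD from its copy number.

    A junction of two distinct ancestral chromosomes present in two or more
    duplicated copies must predate the duplication; a junction present in
    exactly one copy most likely formed after it.  Singleton junctions whose
    flanking ends are engaged in a *different* junction elsewhere are
    reported as ambiguous (the sister junction may have been disrupted by a
    later crossover) rather than misclassified.  Junctions already present
    in the ancestor are skipped.  Requires at least one WGD/WGT in the
    history of ``post_wgd``.
    """
    if not any(h in ("WGD", "WGT") for h in post_wgd.history):
        raise ValidationError(
            "fusion-timing rule needs a whole-genome duplication in the history"
        )
    ancestor_keys = {frozenset(j) for j in _junctions(ancestor)}
    junctions = _junctions(post_wgd)
    counts: dict[frozenset, int] = {}
    reps: dict[frozenset, tuple[tuple[str, float], tuple[str, float]]] = {}
    for j in junctions:
        key = frozenset(j)
        if key in ancestor_keys:
            continue
        counts[key] = counts.get(key, 0) + 1
        reps.setdefault(key, j)
    # which (ancestral end) coordinates participate in which junctions
    end_usage: dict[tuple[str, float], set[frozenset]] = {}
    for key in counts:
        for end in key:
            end_usage.setdefault(end, set()).add(key)
    calls = []
    for key, n in counts.items():
        (a, ca), (b, cb) = sorted(reps[key])
        if n >= 2:
            timing = "pre_wgd"
        else:
            engaged_elsewhere = any(
                len(end_usage[end]) > 1 for end in key
            )
            timing = "ambiguous" if engaged_elsewhere else "post_wgd"
        calls.append(
            AdjacencyCall(
                chrom_a=a, coord_a=ca, chrom_b=b, coord_b=cb, copies=n, timing=timing
            )
        )
    return sorted(calls, key=lambda c: (c.chrom_a, c.chrom_b, c.coord_a))


def write_karyotype(k: Karyotype, path, satellites_path=None) -> None:
    write_tsv(
        path,
        ["chrom", "seg_index", "ancestral_chrom", "span_lo", "span_hi", "orientation"],
        (
            [c.name, i, s.ancestral_chrom, f"{s.lo:.9g}", f"{s.hi:.9g}", s.orientation]
            for c in k.chromosomes
            for i, s in enumerate(c.segments)
        ),
    )
    if satellites_path is not None:
        write_tsv(
            satellites_path,
            ["label", "telomere_a", "telomere_b"],
            ([s.label, s.telomere_a, s.telomere_b] for s in k.satellites),
        )


def read_karyotype(path) -> Karyotype:
    cols, rows = read_tsv(path)
    idx = {c: i for i, c in enumerate(cols)}
    chroms: dict[str, list[tuple[int, Segment]]] = {}
    for r in rows:
        seg = Segment(
            ancestral_chrom=r[idx["ancestral_chrom"]],
            lo=float(r[idx["span_lo"]]),
            hi=float(r[idx["span_hi"]]),
            orientation=int(r[idx["orientation"]]),
        )
        chroms.setdefault(r[idx["chrom"]], []).append((int(r[idx["seg_index"]]), seg))
    return Karyotype(
        chromosomes=[
            Chromosome(name=name, segments=[s for _, s in sorted(segs)])
            for name, segs in chroms.items()
        ]
    )
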
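"""Synthetic two-clade, three-depth population scenario generator.

Emulates the statistical structure of a borehole metagenome study in which six
*Meiothermus*-like populations form two clades (surface-associated ``S`` and
deep-associated ``D``, one population per depth interval in each clade) with
within-clade average nucleotide identity ~99.99% and between-clade ANI ~84%.
Each population carries strain-level single-nucleotide polymorphism, optional
recombination tracts copied from a donor population, and mobile genetic
elements that are either vertically inherited (pre-divergence) or horizontally
transferred (post-divergence).

Every operation is deterministic given the configuration seed; the generator
records a :class:`TruthSet` so downstream variant calling, shared-SNV
identification and ANI comparison can be scored against ground truth.

Coordinates are 0-based half-open internally and 1-based closed in GFF3 output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODES[ord(_b)] = _i

#: canonical population labels: clade letter + maximum depth of the interval
MAG_LABELS = ("S-30", "S-65", "S-132", "D-30", "D-65", "D-132")
DEPTH_INTERVALS = {"30": "0-30", "65": "41-65", "132": "108-132"}
#: abundance designations of the six populations (rare = the minority clade
#: population within its depth interval)
ABUNDANCE_CLASSES = {
    "S-30": "abundant",
    "S-65": "rare",
    "S-132": "rare",
    "D-30": "rare",
    "D-65": "abundant",
    "D-132": "abundant",
}

_STOP_CODONS = ("TAA", "TAG", "TGA")

# per-operation seed-stream identifiers, so composed stages never share a stream
_STAGE_ANCESTOR = 1
_STAGE_DIVERGE = 2
_STAGE_POLY = 3
_STAGE_RECOMB = 4
_STAGE_MGE = 5
_STAGE_READS = 6


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = _BASE_CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), BASES.encode())
    ).decode()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Orf:
    """A protein-coding interval on a contig (0-based, half-open)."""

    orf_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.orf_id}: empty interval")
        if (self.end - self.start) % 3:
            raise ValueError(f"{self.orf_id}: length not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.orf_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MagRecord:
    """One population genome: contigs, ORF annotation and metadata.

    ``proteins``/``orf_nt_sequences`` are derived from the current contig
    sequences on demand, so sequence edits (recombination, element transfer)
    can never leave stale translations behind.
    """

    mag_id: str
    clade: str
    depth_interval: str
    abundance_class: str
    contigs: dict[str, str]
    orfs: list[Orf]
    completeness: float = 1.0

    def __post_init__(self):
        if not (0 < self.completeness <= 1):
            raise ValueError("completeness must be in (0, 1]")
        for orf in self.orfs:
            if orf.contig not in self.contigs:
                raise ValueError(f"{orf.orf_id}: unknown contig {orf.contig}")
            if orf.end > len(self.contigs[orf.contig]):
                raise ValueError(f"{orf.orf_id}: extends past contig end")

    def orf_nt_sequence(self, orf: Orf) -> str:
        seq = self.contigs[orf.contig][orf.start:orf.end]
        return seq if orf.strand == "+" else revcomp(seq)

    def orf_nt_sequences(self) -> dict[str, str]:
        return {o.orf_id: self.orf_nt_sequence(o) for o in self.orfs}

    def protein_sequences(self) -> dict[str, str]:
        out = {}
        for orf in self.orfs:
            aa = str(Seq(self.orf_nt_sequence(orf)).translate())
            out[orf.orf_id] = aa[:-1] if aa.endswith("*") else aa
        return out

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def orf_at(self, contig: str, position: int) -> Orf | None:
        for orf in self.orfs:
            if orf.contig == contig and orf.start <= position < orf.end:
                return orf
        return None


@dataclass(frozen=True)
class TrueSnv:
    mag_id: str
    contig: str
    position: int
    consensus_base: str
    variant_base: str
    frequency: float


@dataclass(frozen=True)
class RecombTract:
    donor: str
    recipient: str
    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class MgeInsertion:
    mag_id: str
    mge_name: str
    contig: str
    start: int
    end: int
    sequence: str
    truncated: bool = False


@dataclass
class TruthSet:
    """Ground truth for scoring the analysis stages."""

    true_snvs: list[TrueSnv] = field(default_factory=list)
    recomb_tracts: list[RecombTract] = field(default_factory=list)
    mge_insertions: list[MgeInsertion] = field(default_factory=list)

    def snvs_for(self, mag_id: str) -> list[TrueSnv]:
        return [s for s in self.true_snvs if s.mag_id == mag_id]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic scenario.

    Defaults are the study conditions at desk scale: a 240 kb six-contig
    genome per population, two clades at 16% nucleotide divergence
    (between-clade ANI ~84%), populations at 5e-5 divergence from their clade
    reference (pairwise within-clade ANI ~99.99%), an in-ORF polymorphism
    rate of 5e-3 per bp giving a per-population SNV burden of order 10^3, and
    50x paired-end coverage with 0.1% base error.
    """

    seed: int = 0
    contig_lengths: tuple[int, ...] = (40_000,) * 6
    orf_fraction: float = 0.85
    orf_min_codons: int = 100
    orf_max_codons: int = 400
    clade_divergence: float = 0.16
    within_clade_divergence: float = 5e-5
    snv_rate: float = 5e-3
    snv_freq_range: tuple[float, float] = (0.05, 0.35)
    n_recomb_tracts: int = 2
    tract_mean: float = 8_000.0
    tract_sd: float = 1_000.0
    recomb_pairs: tuple[tuple[str, str], ...] = (("D-65", "S-132"),)
    n_mges: int = 2
    mge_length: int = 1_200
    mge_repeat_length: int = 25
    mge_transfers: tuple[tuple[str, str, str], ...] = (("mge02", "D-132", "S-65"),)
    coverage: float = 50.0
    read_length: int = 150
    insert_median: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 1e-3
    mapq_default: int = 30
    zero_mapq_fraction: float = 0.02

    def __post_init__(self):
        rates = {
            "orf_fraction": self.orf_fraction,
            "clade_divergence": self.clade_divergence,
            "within_clade_divergence": self.within_clade_divergence,
            "error_rate": self.error_rate,
            "zero_mapq_fraction": self.zero_mapq_fraction,
        }
        for name, value in rates.items():
            if not (0 <= value <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.snv_rate < 0:
            raise ConfigError("snv_rate must be >= 0")
        lo, hi = self.snv_freq_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("snv_freq_range must lie inside (0, 1)")
        if any(l <= 0 for l in self.contig_lengths):
            raise ConfigError("contig lengths must be positive")
        if self.orf_min_codons < 3 or self.orf_max_codons < self.orf_min_codons:
            raise ConfigError("invalid ORF codon bounds")
        for v, name in ((self.coverage, "coverage"), (self.read_length, "read_length")):
            if v < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_recomb_tracts < 0 or self.n_mges < 0:
            raise ConfigError("counts must be >= 0")
        if self.mge_length <= 2 * self.mge_repeat_length:
            raise ConfigError("mge_length must exceed twice the repeat length")

    def rng(self, stage: int, extra: Sequence[int] = ()) -> np.random.Generator:
        """Deterministic per-stage random stream."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(stage), *map(int, extra)])
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("contig_lengths", "snv_freq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("recomb_pairs", "mge_transfers"):
            if key in raw:
                raw[key] = tuple(tuple(x) for x in raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome construction


def _sense_codons() -> np.ndarray:
    codons = []
    for a in range(4):
        for b in range(4):
            for c in range(4):
                if decode(np.array([a, b, c])) not in _STOP_CODONS:
                    codons.append((a, b, c))
    return np.array(codons, dtype=np.uint8)


_SENSE = _sense_codons()
_ATG = encode("ATG")
_STOPS = np.array([encode(s) for s in _STOP_CODONS], dtype=np.uint8)


def _layout_orfs(length: int, config: SimulationConfig, rng: np.random.Generator):
    """Choose ORF intervals covering ~orf_fraction of a contig.

    ORF lengths are drawn until their total reaches the per-contig target,
    the last ORF being trimmed (codon-granular) to land on it; intergenic
    space is then split uniformly into the gaps between ORFs.
    """
    target = int(round(config.orf_fraction * length))
    lengths: list[int] = []
    total = 0
    min_len = 3 * config.orf_min_codons
    while total < target:
        n_codons = int(rng.integers(config.orf_min_codons, config.orf_max_codons + 1))
        l = 3 * n_codons
        if total + l > target:
            l = 3 * ((target - total) // 3)
            if l < min_len:
                break
        lengths.append(l)
        total += l
    gap_total = length - total
    n_gaps = len(lengths) + 1
    gaps = rng.multinomial(gap_total, np.full(n_gaps, 1.0 / n_gaps))
    intervals = []
    pos = 0
    for l, g in zip(lengths, gaps[:-1]):
        pos += int(g)
        intervals.append((pos, pos + l))
        pos += l
    return intervals


def simulate_ancestor(config: SimulationConfig) -> MagRecord:
    """Instantiate the founder genome from which all six populations descend.

    Contigs carry non-overlapping forward-strand ORFs (ATG start, sense-codon
    body, stop codon) tiling ~``orf_fraction`` of the sequence.
    """
    rng = config.rng(_STAGE_ANCESTOR)
    contigs: dict[str, str] = {}
    orfs: list[Orf] = []
    for ci, length in enumerate(config.contig_lengths):
        name = f"c{ci:02d}"
        seq = rng.integers(0, 4, size=length, dtype=np.uint8)
        if config.orf_fraction > 0:
            for oi, (start, end) in enumerate(_layout_orfs(length, config, rng)):
                n_codons = (end - start) // 3
                body = _SENSE[rng.integers(0, len(_SENSE), size=n_codons - 2)].ravel()
                stop = _STOPS[rng.integers(0, len(_STOPS))]
                seq[start:end] = np.concatenate([_ATG, body, stop])
                orfs.append(Orf(f"orf_{name}_{oi:04d}", name, start, end))
        contigs[name] = decode(seq)
    return MagRecord(
        mag_id="ancestor",
        clade="ancestral",
        depth_interval="none",
        abundance_class="abundant",
        contigs=contigs,
        orfs=orfs,
    )


def _mutate(contigs: dict[str, str], rate: float, rng: np.random.Generator):
    """Substitute bases at ``rate`` per site, uniform over the 3 alternatives."""
    out = {}
    n_subs = 0
    for name, seq in contigs.items():
        codes = encode(seq)
        mask = rng.random(len(codes)) < rate
        n = int(mask.sum())
        if n:
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
        out[name] = decode(codes)
        n_subs += n
    return out, n_subs


def diverge_populations(
    ancestor: MagRecord, config: SimulationConfig
) -> tuple[dict[str, MagRecord], dict]:
    """Derive the six populations: two clades, three depth intervals each.

    The ``S`` clade reference is the ancestor itself; the ``D`` clade
    reference carries substitutions at ``clade_divergence`` per site (so
    between-clade identity ~= 1 - clade_divergence, checked positionally).
    Each population then diverges from its clade reference at
    ``within_clade_divergence`` per site, so a within-clade *pair* sits at
    ~2x that distance (~99.99% ANI at the 5e-5 default).
    """
    rng = config.rng(_STAGE_DIVERGE)
    refs = {"S": dict(ancestor.contigs)}
    refs["D"], n_clade = _mutate(ancestor.contigs, config.clade_divergence, rng)
    lineage: dict = {"clade_divergence_sites": n_clade, "within": {}}
    mags: dict[str, MagRecord] = {}
    for label in MAG_LABELS:
        clade, depth = label.split("-")
        contigs, n_within = _mutate(refs[clade], config.within_clade_divergence, rng)
        lineage["within"][label] = n_within
        mags[label] = MagRecord(
            mag_id=label,
            clade=clade,
            depth_interval=DEPTH_INTERVALS[depth],
            abundance_class=ABUNDANCE_CLASSES[label],
            contigs=contigs,
            orfs=list(ancestor.orfs),
        )
    return mags, lineage


def inject_polymorphisms(
    mag: MagRecord, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TrueSnv]:
    """Draw segregating sites uniformly over ORF positions.

    The contig sequence is the consensus; each polymorphic site gets a variant
    base (uniform over the 3 alternatives) at a frequency drawn from
    ``snv_freq_range``. The population's reads, not its consensus, carry the
    variant.
    """
    if rng is None:
        rng = config.rng(_STAGE_POLY, [_label_key(mag.mag_id)])
    positions = [
        (orf.contig, p) for orf in mag.orfs for p in range(orf.start, orf.end)
    ]
    if not positions or config.snv_rate == 0:
        return []
    n = int(rng.poisson(config.snv_rate * len(positions)))
    n = min(n, len(positions))
    idx = rng.choice(len(positions), size=n, replace=False)
    lo, hi = config.snv_freq_range
    freqs = rng.uniform(lo, hi, size=n)
    offsets = rng.integers(1, 4, size=n)
    snvs = []
    for i, (k, f, off) in enumerate(zip(idx, freqs, offsets)):
        contig, pos = positions[int(k)]
        cons = mag.contigs[contig][pos]
        var = BASES[(BASES.index(cons) + int(off)) % 4]
        snvs.append(TrueSnv(mag.mag_id, contig, pos, cons, var, float(f)))
    return snvs


def _label_key(label: str) -> int:
    return int.from_bytes(label.encode(), "big") % (2**31)


def _snap_to_orf_boundaries(mag: MagRecord, contig: str, start: int, end: int):
    """Expand a tract outward so its endpoints never fall inside an ORF."""
    for orf in mag.orfs:
        if orf.contig != contig:
            continue
        if orf.start < start < orf.end:
            start = orf.start
        if orf.start < end < orf.end:
            end = orf.end
    return start, end


def inject_recombination(
    donor: MagRecord,
    recipient: MagRecord,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[RecombTract]:
    """Copy tracts of donor sequence into the recipient genome.

    Tract endpoints are snapped outward to ORF boundaries so a tract never
    splits a coding sequence. Donor polymorphisms inside the tract are copied
    into the recipient truth with identical consensus/variant bases — the
    ground-truth "shared SNV with the same substitution" signal — while any
    pre-existing recipient polymorphism inside the tract is dropped (the
    tract is modeled as having replaced the recipient haplotypes there).
    """
    if rng is None:
        rng = config.rng(_STAGE_RECOMB, [_label_key(donor.mag_id), _label_key(recipient.mag_id)])
    if set(donor.contigs) != set(recipient.contigs):
        raise ConfigError("donor and recipient must share contig naming")
    tracts: list[RecombTract] = []
    contig_names = sorted(donor.contigs)
    for _ in range(config.n_recomb_tracts):
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        clen = len(recipient.contigs[contig])
        length = int(np.clip(rng.normal(config.tract_mean, config.tract_sd), 300, None))
        if length > clen:
            raise ConfigError(
                f"tract length {length} exceeds contig {contig} length {clen}"
            )
        start = int(rng.integers(0, clen - length + 1))
        start, end = _snap_to_orf_boundaries(recipient, contig, start, start + length)
        recipient.contigs[contig] = (
            recipient.contigs[contig][:start]
            + donor.contigs[contig][start:end]
            + recipient.contigs[contig][end:]
        )
        truth.true_snvs = [
            s
            for s in truth.true_snvs
            if not (
                s.mag_id == recipient.mag_id
                and s.contig == contig
                and start <= s.position < end
            )
        ]
        for s in truth.snvs_for(donor.mag_id):
            if s.contig == contig and start <= s.position < end:
                truth.true_snvs.append(
                    TrueSnv(
                        recipient.mag_id, contig, s.position,
                        s.consensus_base, s.variant_base, s.frequency,
                    )
                )
        # refresh any recipient element record the tract overwrote
        truth.mge_insertions = [
            m
            if not (m.mag_id == recipient.mag_id and m.contig == contig
                    and m.start < end and start < m.end)
            else MgeInsertion(m.mag_id, m.mge_name, m.contig, m.start, m.end,
                              recipient.contigs[contig][m.start:m.end], m.truncated)
            for m in truth.mge_insertions
        ]
        tract = RecombTract(donor.mag_id, recipient.mag_id, contig, start, end)
        tracts.append(tract)
        truth.recomb_tracts.append(tract)
    return tracts


# ---------------------------------------------------------------------------
# mobile genetic elements


def make_mge_sequence(rng: np.random.Generator, length: int, repeat_length: int) -> str:
    """Random cargo flanked by inverted repeats (right = revcomp of left)."""
    if length <= 2 * repeat_length:
        raise ConfigError("element length must exceed twice the repeat length")
    left = decode(rng.integers(0, 4, size=repeat_length, dtype=np.uint8))
    cargo = decode(rng.integers(0, 4, size=length - 2 * repeat_length, dtype=np.uint8))
    return left + cargo + revcomp(left)


def insert_element(
    mag: MagRecord,
    truth: TruthSet,
    mge_name: str,
    sequence: str,
    contig: str,
    position: int,
    truncate_fraction: float | None = None,
) -> MgeInsertion:
    """Splice an element into a contig, shifting downstream annotation.

    The insertion point must be intergenic and must not overlap a previously
    inserted element. ORF intervals, truth SNVs and prior element intervals
    downstream of the insertion point are shifted by the element length.
    """
    if mag.orf_at(contig, position) is not None:
        raise ConfigError(f"insertion point {contig}:{position} lies inside an ORF")
    seq = sequence
    truncated = False
    if truncate_fraction is not None:
        if not (0 < truncate_fraction <= 1):
            raise ConfigError("truncate_fraction must be in (0, 1]")
        seq = sequence[: int(round(truncate_fraction * len(sequence)))]
        truncated = truncate_fraction < 1
    for m in truth.mge_insertions:
        if m.mag_id == mag.mag_id and m.contig == contig and m.start <= position < m.end:
            raise ConfigError(f"insertion at {contig}:{position} overlaps element {m.mge_name}")
    n = len(seq)
    old = mag.contigs[contig]
    mag.contigs[contig] = old[:position] + seq + old[position:]
    mag.orfs = [
        o
        if o.contig != contig or o.start < position
        else Orf(o.orf_id, o.contig, o.start + n, o.end + n, o.strand)
        for o in mag.orfs
    ]
    truth.true_snvs = [
        s
        if s.mag_id != mag.mag_id or s.contig != contig or s.position < position
        else TrueSnv(s.mag_id, s.contig, s.position + n, s.consensus_base, s.variant_base, s.frequency)
        for s in truth.true_snvs
    ]
    truth.mge_insertions = [
        m
        if m.mag_id != mag.mag_id or m.contig != contig or m.start < position
        else MgeInsertion(m.mag_id, m.mge_name, m.contig, m.start + n, m.end + n, m.sequence, m.truncated)
        for m in truth.mge_insertions
    ]
    rec = MgeInsertion(mag.mag_id, mge_name, contig, position, position + n, seq, truncated)
    truth.mge_insertions.append(rec)
    return rec


def insert_ancestral_mges(
    ancestor: MagRecord, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MgeInsertion]:
    """Insert ``n_mges`` elements into the founder (pre-divergence).

    Returns the founder's insertion records (final coordinates); after
    divergence the six populations inherit diverged copies at the same
    coordinates, since divergence introduces no indels.
    """
    if rng is None:
        rng = config.rng(_STAGE_MGE)
    scratch = TruthSet()
    contig_names = sorted(ancestor.contigs)
    for i in range(config.n_mges):
        name = f"mge{i + 1:02d}"
        seq = make_mge_sequence(rng, config.mge_length, config.mge_repeat_length)
        contig = contig_names[i % len(contig_names)]
        # pick an intergenic position
        for _ in range(1000):
            pos = int(rng.integers(0, len(ancestor.contigs[contig])))
            if ancestor.orf_at(contig, pos) is None and not any(
                m.contig == contig and m.start <= pos < m.end for m in scratch.mge_insertions
            ):
                break
        else:  # pragma: no cover - orf_fraction ~1 pathological configs
            raise ConfigError(f"no intergenic insertion point found on {contig}")
        insert_element(ancestor, scratch, name, seq, contig, pos)
    return list(scratch.mge_insertions)


def transfer_mge(
    truth: TruthSet, mags: Mapping[str, MagRecord], mge_name: str, donor: str, recipient: str
) -> None:
    """Overwrite the recipient's element copy with the donor's (same locus)."""
    def _find(mag_id):
        for m in truth.mge_insertions:
            if m.mag_id == mag_id and m.mge_name == mge_name:
                return m
        raise KeyError(f"{mge_name} not recorded for {mag_id}")

    src, dst = _find(donor), _find(recipient)
    if len(src.sequence) != len(dst.sequence):
        raise ConfigError("transfer between differing-length copies is unsupported")
    mag = mags[recipient]
    mag.contigs[dst.contig] = (
        mag.contigs[dst.contig][: dst.start] + src.sequence + mag.contigs[dst.contig][dst.end :]
    )
    truth.mge_insertions = [
        m
        if not (m.mag_id == recipient and m.mge_name == mge_name)
        else MgeInsertion(recipient, mge_name, dst.contig, dst.start, dst.end, src.sequence)
        for m in truth.mge_insertions
    ]


# ---------------------------------------------------------------------------
# read-pair simulation


def simulate_read_pairs(
    mag: MagRecord,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample mapped read-pair observations to ~``coverage`` mean depth.

    At a polymorphic site a read carries the variant base with probability
    equal to the truth frequency; substitution errors are applied at
    ``error_rate`` per base; insert sizes follow a clipped normal. Mapping
    quality is ``mapq_default`` with ``zero_mapq_fraction`` of pairs at 0 to
    exercise the mapQ filter. Pair identity to the reference is computed over
    both mates after all edits.
    """
    if rng is None:
        rng = config.rng(_STAGE_READS, [_label_key(mag.mag_id)])
    rl = config.read_length
    if config.coverage > 0 and rl > min(len(s) for s in mag.contigs.values()):
        raise ConfigError("read_length exceeds the shortest contig")
    frames = []
    snvs_by_contig: dict[str, list[TrueSnv]] = {}
    for s in truth.snvs_for(mag.mag_id):
        snvs_by_contig.setdefault(s.contig, []).append(s)
    for contig in sorted(mag.contigs):
        ref = encode(mag.contigs[contig])
        L = len(ref)
        n_pairs = int(round(config.coverage * L / (2 * rl)))
        if n_pairs == 0:
            continue
        inserts = rng.normal(config.insert_median, config.insert_sd, size=n_pairs)
        inserts = np.clip(np.rint(inserts), rl, L).astype(np.int64)
        starts = rng.integers(0, L - inserts + 1)
        m2_starts = starts + inserts - rl
        offs = np.arange(rl)
        reads1 = ref[starts[:, None] + offs]
        reads2 = ref[m2_starts[:, None] + offs]
        for s in snvs_by_contig.get(contig, []):
            vcode = _BASE_CODES[ord(s.variant_base)]
            for reads, st in ((reads1, starts), (reads2, m2_starts)):
                cover = (st <= s.position) & (s.position < st + rl)
                rows = np.nonzero(cover)[0]
                carry = rows[rng.random(rows.size) < s.frequency]
                reads[carry, s.position - st[carry]] = vcode
        if config.error_rate > 0:
            for reads in (reads1, reads2):
                err = rng.random(reads.shape) < config.error_rate
                n_err = int(err.sum())
                reads[err] = (reads[err] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
        matches = (reads1 == ref[starts[:, None] + offs]).sum(axis=1)
        matches = matches + (reads2 == ref[m2_starts[:, None] + offs]).sum(axis=1)
        identity = matches / (2 * rl)
        mapq = np.full(n_pairs, config.mapq_default, dtype=np.int64)
        mapq[rng.random(n_pairs) < config.zero_mapq_fraction] = 0
        trans = bytes.maketrans(bytes(range(4)), BASES.encode())
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": [f"{contig}:{i}" for i in range(n_pairs)],
                    "contig": contig,
                    "mate1_start": starts,
                    "mate2_start": m2_starts,
                    "insert_size": inserts,
                    "mapq1": mapq,
                    "mapq2": mapq,
                    "pair_identity": identity,
                    "bases1": [r.tobytes().translate(trans).decode() for r in reads1],
                    "bases2": [r.tobytes().translate(trans).decode() for r in reads2],
                }
            )
        )
    if not frames:
        return empty_read_pair_table()
    return pd.concat(frames, ignore_index=True)


def empty_read_pair_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": pd.Series(dtype=str),
            "contig": pd.Series(dtype=str),
            "mate1_start": pd.Series(dtype=np.int64),
            "mate2_start": pd.Series(dtype=np.int64),
            "insert_size": pd.Series(dtype=np.int64),
            "mapq1": pd.Series(dtype=np.int64),
            "mapq2": pd.Series(dtype=np.int64),
            "pair_identity": pd.Series(dtype=float),
            "bases1": pd.Series(dtype=str),
            "bases2": pd.Series(dtype=str),
        }
    )


# ---------------------------------------------------------------------------
# full scenario


def simulate_scenario(
    config: SimulationConfig,
) -> tuple[dict[str, MagRecord], TruthSet, dict]:
    """Run the full generator: founder -> elements -> clades -> polymorphism
    -> recombination -> element transfer.

    Returns the six populations, the truth set, and the lineage record.
    """
    ancestor = simulate_ancestor(config)
    truth = TruthSet()
    placements: list[MgeInsertion] = []
    if config.n_mges:
        placements = insert_ancestral_mges(ancestor, config, config.rng(_STAGE_MGE))
    mags, lineage = diverge_populations(ancestor, config)
    # inherited element copies, re-sliced from each diverged genome
    for label, mag in mags.items():
        for p in placements:
            truth.mge_insertions.append(
                MgeInsertion(label, p.mge_name, p.contig, p.start, p.end,
                             mag.contigs[p.contig][p.start:p.end])
            )
    for label, mag in mags.items():
        truth.true_snvs.extend(inject_polymorphisms(mag, config))
    for donor_id, recipient_id in config.recomb_pairs:
        if config.n_recomb_tracts:
            inject_recombination(mags[donor_id], mags[recipient_id], truth, config)
    for mge_name, donor_id, recipient_id in config.mge_transfers:
        if any(m.mge_name == mge_name for m in truth.mge_insertions):
            transfer_mge(truth, mags, mge_name, donor_id, recipient_id)
    return mags, truth, lineage


def truth_snv_table(mag: MagRecord, truth: TruthSet) -> pd.DataFrame:
    """Ground-truth polymorphisms of one population, shaped like a called
    SNV table (for truth-level runs of the shared-SNV stages)."""
    rows = [
        {
            "mag_id": s.mag_id,
            "contig": s.contig,
            "position": s.position,
            "consensus_base": s.consensus_base,
            "variant_base": s.variant_base,
            "variant_frequency": s.frequency,
            "depth": np.nan,
        }
        for s in truth.snvs_for(mag.mag_id)
    ]
    cols = ["mag_id", "contig", "position", "consensus_base", "variant_base",
            "variant_frequency", "depth"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# file I/O


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(mag: MagRecord, path: str | Path) -> None:
    """1-based, closed-interval CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in mag.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for o in mag.orfs:
            fh.write(
                f"{o.contig}\tparasnv\tCDS\t{o.start + 1}\t{o.end}\t.\t{o.strand}\t0\t"
                f"ID={o.orf_id}\n"
            )


def read_gff3(path: str | Path) -> list[Orf]:
    orfs = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        orfs.append(Orf(attrs.get("ID", f"{f[0]}_{f[3]}"), f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return orfs


def write_protein_fasta(mag: MagRecord, path: str | Path) -> None:
    write_fasta(mag.protein_sequences(), path)


def write_read_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "contig": str,
                                            "bases1": str, "bases2": str})
    return df if len(df) else empty_read_pair_table()


def write_truth(truth: TruthSet, directory: str | Path) -> None:
    directory = Path(directory)
    pd.DataFrame([dataclasses.asdict(s) for s in truth.true_snvs]).to_csv(
        directory / "truth_snvs.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(t) for t in truth.recomb_tracts]).to_csv(
        directory / "truth_tracts.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(m) for m in truth.mge_insertions]).to_csv(
        directory / "truth_mges.tsv", sep="\t", index=False
    )
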
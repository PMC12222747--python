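"""Synthetic HNWD-like alleles with planted repeat architectures.

Generates nucleotide gene sequences built as flank + N tandem 126-bp
WD40 repeat units + flank, where every repeat is a reverse translation
of a shared 42-aa consensus with variation confined to the seven
hypervariable codons.  The planted truth (ordered variant IDs, their
7-aa signatures, and any structural or disrupting mutations) is
recorded alongside, so detection and classification can be tested
against known answers.

Structural mutations model concerted evolution by unequal crossover
(tandem duplication or deletion of a contiguous block of repeats);
disruptions model the stop codons and single-bp frameshifting
deletions seen in natural non-functional alleles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    AA_ALPHABET,
    HET_E_CONSENSUS_AA,
    HYPERVARIABLE_POSITIONS,
    REPEAT_PERIOD_NT,
    STOP_CODONS,
)

__all__ = [
    "SimulationConfig",
    "MutationEvent",
    "PlantedAllele",
    "reverse_translate",
    "build_variant_library",
    "generate_allele",
    "apply_unequal_crossover",
    "inject_disruption",
    "write_simulation",
    "read_truth_table",
    "simulate_cohort",
]


def _first_codon_table() -> dict[str, str]:
    """aa -> lexicographically first codon of the standard genetic code."""
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    table: dict[str, str] = {}
    for codon in sorted(fwd):
        aa = fwd[codon]
        table.setdefault(aa, codon)
    return table


_AA_TO_CODON = _first_codon_table()


def reverse_translate(aa_seq: str) -> str:
    """Deterministic reverse translation: first codon in lexicographic
    order of the standard table, per amino acid."""
    try:
        return "".join(_AA_TO_CODON[aa] for aa in aa_seq)
    except KeyError as exc:  # pragma: no cover - guarded by config validation
        raise ValueError(f"cannot reverse-translate residue {exc}") from exc


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic allele generator.

    ``background_sub_rate`` is a per-nucleotide substitution probability
    applied outside the hypervariable codons, emulating the residual
    (>80% identity) divergence among a gene's own repeats.
    """

    seed: int = 0
    repeat_period_nt: int = REPEAT_PERIOD_NT
    consensus_aa: str = HET_E_CONSENSUS_AA
    hypervariable_positions: tuple[int, ...] = HYPERVARIABLE_POSITIONS
    variant_library_size: int = 24
    hypervariable_alphabet: str = AA_ALPHABET
    background_sub_rate: float = 0.0
    flank_length_nt: int = 500
    codon_choice: str = "lexicographic"

    def __post_init__(self) -> None:
        if self.repeat_period_nt != 3 * len(self.consensus_aa):
            raise ValueError(
                "repeat_period_nt must equal 3 x consensus length "
                f"({self.repeat_period_nt} != 3*{len(self.consensus_aa)})"
            )
        if not all(1 <= p <= len(self.consensus_aa) for p in self.hypervariable_positions):
            raise ValueError("hypervariable positions must lie within the repeat")
        if not 0.0 <= self.background_sub_rate <= 1.0:
            raise ValueError("background_sub_rate must be in [0, 1]")
        if self.flank_length_nt < 0:
            raise ValueError("flank_length_nt must be >= 0")
        if self.codon_choice != "lexicographic":
            raise ValueError(f"unknown codon_choice: {self.codon_choice!r}")
        bad = set(self.consensus_aa) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"consensus contains non-standard residues: {bad}")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the root seed (stable across runs)."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class MutationEvent:
    kind: str  # point | duplication | deletion | stop | frameshift
    repeat_index: int
    detail: str = ""


@dataclass
class PlantedAllele:
    """A synthetic gene with its planted truth.

    ``variant_ids`` are 1-based indices into the variant library;
    ``truth_signatures`` the corresponding 7-aa signatures.  Repeats are
    stored per unit so structural edits stay coordinate-exact.
    """

    allele_id: str
    variant_ids: list[int]
    repeat_nt_seqs: list[str]
    truth_signatures: list[str]
    flank5: str
    flank3: str
    events: list[MutationEvent] = field(default_factory=list)

    @property
    def full_sequence(self) -> str:
        return self.flank5 + "".join(self.repeat_nt_seqs) + self.flank3

    @property
    def n_repeats(self) -> int:
        return len(self.variant_ids)

    def repeat_coordinates(self) -> list[tuple[int, int]]:
        """0-based half-open nt coordinates of each repeat on full_sequence."""
        coords = []
        pos = len(self.flank5)
        for seq in self.repeat_nt_seqs:
            coords.append((pos, pos + len(seq)))
            pos += len(seq)
        return coords


def build_variant_library(config: SimulationConfig) -> list[tuple[str, str]]:
    """Sample the repeat-variant space: a list of (signature, repeat_nt).

    Entry 1 is always the consensus signature itself; further entries
    are drawn without replacement from the product space of the
    hypervariable alphabet over the seven positions, so all signatures
    are pairwise distinct.  Deterministic under the config seed.
    """
    positions = config.hypervariable_positions
    alphabet = sorted(set(config.hypervariable_alphabet))
    space = len(alphabet) ** len(positions)
    if config.variant_library_size > space:
        raise ValueError(
            f"alphabet supports only {space} distinct signatures, "
            f"{config.variant_library_size} requested"
        )
    consensus_sig = "".join(config.consensus_aa[p - 1] for p in positions)
    rng = config.rng("variant-library")
    signatures = [consensus_sig]
    seen = {consensus_sig}
    while len(signatures) < config.variant_library_size:
        sig = "".join(rng.choice(alphabet) for _ in positions)
        if sig not in seen:
            seen.add(sig)
            signatures.append(sig)
    library = []
    for sig in signatures:
        aa = list(config.consensus_aa)
        for ch, p in zip(sig, positions):
            aa[p - 1] = ch
        library.append((sig, reverse_translate("".join(aa))))
    return library


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _hypervariable_nt_sites(config: SimulationConfig) -> set[int]:
    sites: set[int] = set()
    for p in config.hypervariable_positions:
        sites.update(range(3 * (p - 1), 3 * p))
    return sites


def _apply_background(
    repeat_nt: str, rng: np.random.Generator, rate: float, protected: set[int]
) -> str:
    """Point substitutions outside hypervariable codons, never creating
    an in-frame stop (disruptions are planted explicitly, not sampled)."""
    if rate <= 0:
        return repeat_nt
    seq = list(repeat_nt)
    for i in range(len(seq)):
        if i in protected or rng.random() >= rate:
            continue
        choices = [b for b in "ACGT" if b != seq[i]]
        old = seq[i]
        seq[i] = rng.choice(choices)
        codon_start = 3 * (i // 3)
        if "".join(seq[codon_start : codon_start + 3]) in STOP_CODONS:
            seq[i] = old
    return "".join(seq)


def generate_allele(
    config: SimulationConfig,
    variant_ids: Sequence[int],
    allele_id: str = "allele",
    library: list[tuple[str, str]] | None = None,
) -> PlantedAllele:
    """Assemble flank + planted repeats + flank for an ordered barcode.

    ``variant_ids`` are 1-based indices into the library built from the
    same config (passed in to avoid rebuilding it per allele).
    """
    if library is None:
        library = build_variant_library(config)
    for vid in variant_ids:
        if not 1 <= vid <= len(library):
            raise ValueError(f"unknown variant ID {vid} (library size {len(library)})")
    rng = config.rng(f"allele:{allele_id}")
    protected = _hypervariable_nt_sites(config)
    repeats, signatures = [], []
    for vid in variant_ids:
        sig, nt = library[vid - 1]
        repeats.append(_apply_background(nt, rng, config.background_sub_rate, protected))
        signatures.append(sig)
    flank5 = _random_flank(rng, config.flank_length_nt)
    flank3 = _random_flank(rng, config.flank_length_nt)
    return PlantedAllele(
        allele_id=allele_id,
        variant_ids=list(variant_ids),
        repeat_nt_seqs=repeats,
        truth_signatures=signatures,
        flank5=flank5,
        flank3=flank3,
    )


def apply_unequal_crossover(
    allele: PlantedAllele, start: int, block_len: int, kind: str
) -> PlantedAllele:
    """Tandem duplication or deletion of repeats [start, start+block_len).

    Duplication inserts an exact copy of the block directly after it;
    deletion removes it.  Returns a new allele; the input is unchanged.
    """
    if kind not in ("duplication", "deletion"):
        raise ValueError(f"kind must be duplication or deletion, got {kind!r}")
    if block_len < 1 or start < 0 or start + block_len > allele.n_repeats:
        raise ValueError(
            f"block [{start}, {start + block_len}) out of range "
            f"for {allele.n_repeats} repeats"
        )
    ids = list(allele.variant_ids)
    nts = list(allele.repeat_nt_seqs)
    sigs = list(allele.truth_signatures)
    stop = start + block_len
    if kind == "duplication":
        ids[stop:stop] = ids[start:stop]
        nts[stop:stop] = nts[start:stop]
        sigs[stop:stop] = sigs[start:stop]
    else:
        del ids[start:stop], nts[start:stop], sigs[start:stop]
    event = MutationEvent(kind, start, f"block_len={block_len}")
    return replace(
        allele,
        variant_ids=ids,
        repeat_nt_seqs=nts,
        truth_signatures=sigs,
        events=allele.events + [event],
    )


def inject_disruption(
    allele: PlantedAllele,
    repeat_index: int,
    kind: str,
    config: SimulationConfig,
) -> PlantedAllele:
    """Plant a stop codon or a single-bp (frameshifting) deletion.

    A stop replaces a sense codon outside the hypervariable codons
    (choice seeded), so the repeat's variant signature stays intact; a
    frameshift deletes one bp inside the repeat.
    """
    if kind not in ("stop", "frameshift"):
        raise ValueError(f"kind must be stop or frameshift, got {kind!r}")
    if not 0 <= repeat_index < allele.n_repeats:
        raise ValueError(f"repeat_index {repeat_index} out of range")
    rng = config.rng(f"disrupt:{allele.allele_id}:{repeat_index}:{kind}")
    nts = list(allele.repeat_nt_seqs)
    target = nts[repeat_index]
    if kind == "stop":
        hv = {p - 1 for p in config.hypervariable_positions}
        candidates = [
            i
            for i in range(len(target) // 3)
            if i not in hv and target[3 * i : 3 * i + 3] not in STOP_CODONS
        ]
        if not candidates:
            raise ValueError("repeat has no mutable sense codon")
        codon_idx = int(rng.choice(candidates))
        stop = str(rng.choice(list(STOP_CODONS)))
        nts[repeat_index] = (
            target[: 3 * codon_idx] + stop + target[3 * codon_idx + 3 :]
        )
        detail = f"codon {codon_idx + 1} -> {stop}"
    else:
        site = int(rng.integers(0, len(target)))
        nts[repeat_index] = target[:site] + target[site + 1 :]
        detail = f"deleted bp {site + 1}"
    event = MutationEvent(kind, repeat_index, detail)
    return replace(allele, repeat_nt_seqs=nts, events=allele.events + [event])


def _format_events(events: Iterable[MutationEvent]) -> str:
    return ";".join(f"{e.kind}@{e.repeat_index}({e.detail})" for e in events) or "."


def write_simulation(
    alleles: Sequence[PlantedAllele], fasta_path: str | Path, truth_path: str | Path
) -> None:
    """Write the cohort as FASTA (full sequences) + truth TSV."""
    records = [
        SeqRecord(Seq(a.full_sequence), id=a.allele_id, description="")
        for a in alleles
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(truth_path, "w") as fh:
        fh.write("allele_id\tn_repeats\tvariant_ids\tsignatures\tevents\n")
        for a in alleles:
            fh.write(
                "\t".join(
                    [
                        a.allele_id,
                        str(a.n_repeats),
                        ",".join(map(str, a.variant_ids)),
                        ",".join(a.truth_signatures),
                        _format_events(a.events),
                    ]
                )
                + "\n"
            )


def read_truth_table(truth_path: str | Path) -> list[dict]:
    """Parse a truth TSV back into records (inverse of write_simulation)."""
    rows = []
    with open(truth_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(
                {
                    "allele_id": vals["allele_id"],
                    "n_repeats": int(vals["n_repeats"]),
                    "variant_ids": (
                        [int(x) for x in vals["variant_ids"].split(",")]
                        if vals["variant_ids"]
                        else []
                    ),
                    "signatures": (
                        vals["signatures"].split(",") if vals["signatures"] else []
                    ),
                    "events": vals["events"],
                }
            )
    return rows


def simulate_cohort(
    config: SimulationConfig,
    n_alleles: int,
    repeats_range: tuple[int, int] = (6, 12),
) -> list[PlantedAllele]:
    """Generate a cohort of alleles with random barcodes drawn from the
    library; repeat counts uniform over ``repeats_range`` (inclusive)."""
    library = build_variant_library(config)
    rng = config.rng("cohort")
    alleles = []
    for i in range(n_alleles):
        n_rep = int(rng.integers(repeats_range[0], repeats_range[1] + 1))
        ids = [int(v) for v in rng.integers(1, len(library) + 1, size=n_rep)]
        alleles.append(
            generate_allele(config, ids, allele_id=f"sim{i:03d}", library=library)
        )
    return alleles
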
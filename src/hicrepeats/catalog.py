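"""Variant classification of detected repeats.

Each repeat is reduced to the amino acids at the seven hypervariable
positions (10, 11, 12, 14, 30, 32, 39 of the 42-aa unit) — its
*signature* — and every distinct signature within a gene family gets a
stable small-integer variant ID, assigned in order of first appearance.
The ordered IDs along an allele form its repeat architecture, the
"barcode" that figures and allele comparisons work with.  IDs carry no
meaning beyond identity; families are catalogued independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import AA_ALPHABET, HYPERVARIABLE_POSITIONS, REPEAT_LENGTH_AA
from .detect import RepeatTrack

__all__ = [
    "SignaturePositions",
    "VariantCatalog",
    "RepeatArchitecture",
    "PositionFrequencyMatrix",
    "extract_signature",
    "classify",
    "build_pfm",
]

SignaturePositions = tuple[int, ...]

PFM_ALPHABET = AA_ALPHABET + "*"  # 20 aa + stop


def extract_signature(
    aa: str, positions: SignaturePositions = HYPERVARIABLE_POSITIONS
) -> str:
    """Signature = the residues at the hypervariable positions.

    Positions beyond the available repeat length (partial repeats)
    yield ``X``.
    """
    return "".join(aa[p - 1] if p <= len(aa) else "X" for p in positions)


@dataclass
class VariantCatalog:
    """Per-family bijection signature <-> integer variant ID.

    IDs start at 1 and follow first-appearance order; persisting and
    re-loading a catalog therefore makes classifications reproducible
    across runs.
    """

    family_id: str
    entries: dict[str, int] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def get_or_assign(self, signature: str) -> int:
        vid = self.entries.get(signature)
        if vid is None:
            vid = len(self.entries) + 1
            self.entries[signature] = vid
            self.counts[vid] = 0
        self.counts[vid] += 1
        return vid

    def signature_of(self, vid: int) -> str:
        for sig, v in self.entries.items():
            if v == vid:
                return sig
        raise KeyError(f"variant ID {vid} not in catalog {self.family_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tvariant_id\tsignature\tcount\n")
            for sig, vid in self.entries.items():
                fh.write(f"{self.family_id}\t{vid}\t{sig}\t{self.counts[vid]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "VariantCatalog":
        cat = None
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("family_id"), "not a catalog TSV"
            rows = []
            for line in fh:
                family, vid, sig, count = line.rstrip("\n").split("\t")
                rows.append((family, int(vid), sig, int(count)))
        rows.sort(key=lambda r: r[1])
        if not rows:
            raise ValueError(f"empty catalog file {path}")
        cat = cls(family_id=rows[0][0])
        for family, vid, sig, count in rows:
            if vid != len(cat.entries) + 1:
                raise ValueError(f"non-contiguous variant IDs in {path}")
            cat.entries[sig] = vid
            cat.counts[vid] = count
        return cat


@dataclass
class RepeatArchitecture:
    """Ordered (variant ID, flags) pairs of one allele."""

    gene_id: str
    family_id: str
    repeats: list[tuple[int, frozenset[str]]] = field(default_factory=list)
    scaffold_breaks: list[int] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[int]:
        return [vid for vid, _ in self.repeats]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def is_disrupted(self) -> bool:
        return any(
            f in flags
            for _, flags in self.repeats
            for f in ("has_stop", "frameshift_suspect")
        )


def classify(
    track: RepeatTrack,
    catalog: VariantCatalog,
    positions: SignaturePositions = HYPERVARIABLE_POSITIONS,
    include_partial: bool = False,
) -> RepeatArchitecture:
    """Map a repeat track to its architecture, growing the catalog.

    Unseen signatures are appended with the next free ID; re-running on
    the same track leaves the catalog's ID assignment unchanged.
    Partial hits (flag ``partial``) are excluded from the barcode by
    default; when included, their X-padded signature gets its own ID
    and the partial flag is carried through.
    """
    arch = RepeatArchitecture(gene_id=track.gene_id, family_id=catalog.family_id)
    for hit in track.hits:
        if "partial" in hit.flags and not include_partial:
            continue
        sig = extract_signature(hit.aa, positions)
        vid = catalog.get_or_assign(sig)
        arch.repeats.append((vid, hit.flags))
    return arch


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue composition of a set of 42-aa repeats.

    ``information_bits[p]`` is log2(20) minus the Shannon entropy of the
    residue distribution at position p — the height a sequence-logo
    column would have.  Hypervariable positions show depressed
    information; fully conserved positions sit at log2(20) ≈ 4.32 bits.
    """

    counts: np.ndarray  # (length, 21)
    alphabet: str = PFM_ALPHABET
    length: int = REPEAT_LENGTH_AA

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    @property
    def information_bits(self) -> np.ndarray:
        freq = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            ent = -np.where(freq > 0, freq * np.log2(freq), 0.0).sum(axis=1)
        info = math.log2(20) - ent
        info[self.counts.sum(axis=1) == 0] = 0.0
        return info

    def write_tsv(self, path: str | Path) -> None:
        info = self.information_bits
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(self.alphabet) + "\tinformation_bits\n")
            for p in range(self.length):
                row = "\t".join(str(int(c)) for c in self.counts[p])
                fh.write(f"{p + 1}\t{row}\t{info[p]:.6f}\n")


def build_pfm(repeats_aa: list[str], length: int = REPEAT_LENGTH_AA) -> PositionFrequencyMatrix:
    """Tally residue counts per position over a set of repeat units."""
    if not repeats_aa:
        raise ValueError("need at least one repeat to build a PFM")
    counts = np.zeros((length, len(PFM_ALPHABET)), dtype=int)
    index = {aa: i for i, aa in enumerate(PFM_ALPHABET)}
    for aa_seq in repeats_aa:
        for p, residue in enumerate(aa_seq[:length]):
            if residue in index:
                counts[p, index[residue]] += 1
    return PositionFrequencyMatrix(counts=counts, length=length)


def write_architectures_tsv(archs: list[RepeatArchitecture], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_id\tvariant_ids\tflags\n")
        for a in archs:
            flags = ";".join(
                ",".join(sorted(f)) or "." for _, f in a.repeats
            )
            fh.write(
                f"{a.gene_id}\t{a.family_id}\t"
                f"{','.join(map(str, a.variant_ids))}\t{flags or '.'}\n"
            )


def read_architectures_tsv(path: str | Path) -> list[RepeatArchitecture]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene_id, family_id, vids, flags = line.rstrip("\n").split("\t")
            ids = [int(x) for x in vids.split(",")] if vids else []
            flag_sets = (
                [
                    frozenset() if f == "." else frozenset(f.split(","))
                    for f in flags.split(";")
                ]
                if flags != "."
                else [frozenset()] * len(ids)
            )
            out.append(
                RepeatArchitecture(
                    gene_id=gene_id,
                    family_id=family_id,
                    repeats=list(zip(ids, flag_sets)),
                )
            )
    return out


__all__ += ["write_architectures_tsv", "read_architectures_tsv"]
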
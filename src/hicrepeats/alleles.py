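"""Comparison and phenotype screening of repeat architectures.

Architectures (ordered variant-ID barcodes) are compared by unit-cost
Levenshtein distance over the variant-ID alphabet, with an explicit
edit script — a duplication by unequal crossover shows up as a single
insertion, a swapped repeat as a single substitution.  Query alleles
are assigned against a reference panel of named architectures with
known phenotypes: only a distance-0 match inherits the panel
phenotype; otherwise the nearest entries are reported ranked, since
similarity alone cannot establish reactivity.

The functionality screen applies the repeat-count rules known from
genetic work — at least 10 HIC repeats for het-e, exactly 11 for
het-d — plus disruption flags.  A "candidate" verdict means the allele
passes these necessary conditions, NOT that it is reactive: an
11-repeat het-e allele is known that triggers no incompatibility
reaction with the common het-c alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .catalog import RepeatArchitecture

__all__ = [
    "EditOp",
    "AllelePanel",
    "AlleleCall",
    "FamilyRule",
    "DEFAULT_FAMILY_RULES",
    "compare_architectures",
    "assign_allele",
    "functionality_screen",
]


@dataclass(frozen=True)
class EditOp:
    """One step of an edit script transforming architecture a into b.

    ``pos_a`` is the 0-based position in a where the operation applies.
    """

    op: str  # substitute | delete | insert
    pos_a: int
    from_id: int | None = None
    to_id: int | None = None


def compare_architectures(
    a: RepeatArchitecture,
    b: RepeatArchitecture,
    force: bool = False,
) -> tuple[int, list[EditOp]]:
    """Minimal unit-cost edit distance between two barcodes, with one
    optimal script (ties prefer substitutions, then deletions, and the
    leftmost placement).

    Architectures spanning scaffold breaks are refused unless
    ``force`` is set, since repeat order across a break is unverified.
    """
    if a.family_id != b.family_id:
        raise ValueError(
            f"cannot compare across families ({a.family_id} vs {b.family_id})"
        )
    if not force and (a.scaffold_breaks or b.scaffold_breaks):
        raise ValueError(
            "architecture spans scaffold breaks; repeat order unverified "
            "(pass force=True to compare anyway)"
        )
    s, t = a.variant_ids, b.variant_ids
    n, m = len(s), len(t)
    # dp[i][j] = distance between s[i:] and t[j:]; suffix DP makes the
    # backtrace emit leftmost edits first.
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][m] = n - i
    for j in range(m + 1):
        dp[n][j] = m - j
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if s[i] == t[j]:
                dp[i][j] = dp[i + 1][j + 1]
            else:
                dp[i][j] = 1 + min(dp[i + 1][j + 1], dp[i + 1][j], dp[i][j + 1])
    script: list[EditOp] = []
    i = j = 0
    while i < n or j < m:
        if i < n and j < m and s[i] == t[j]:
            i += 1
            j += 1
        elif i < n and j < m and dp[i][j] == 1 + dp[i + 1][j + 1]:
            script.append(EditOp("substitute", i, from_id=s[i], to_id=t[j]))
            i += 1
            j += 1
        elif i < n and dp[i][j] == 1 + dp[i + 1][j]:
            script.append(EditOp("delete", i, from_id=s[i]))
            i += 1
        else:
            script.append(EditOp("insert", i, to_id=t[j]))
            j += 1
    return dp[0][0], script


@dataclass
class AllelePanel:
    """Named reference architectures with phenotype labels."""

    entries: dict[str, tuple[str, RepeatArchitecture, str]] = field(
        default_factory=dict
    )

    def add(
        self, name: str, arch: RepeatArchitecture, phenotype: str = "unknown"
    ) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate panel entry {name!r}")
        self.entries[name] = (arch.family_id, arch, phenotype)

    def for_family(self, family_id: str) -> list[tuple[str, RepeatArchitecture, str]]:
        return [
            (name, arch, pheno)
            for name, (fam, arch, pheno) in self.entries.items()
            if fam == family_id
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tfamily_id\tphenotype\tvariant_ids\n")
            for name, (fam, arch, pheno) in self.entries.items():
                fh.write(
                    f"{name}\t{fam}\t{pheno}\t"
                    f"{','.join(map(str, arch.variant_ids))}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AllelePanel":
        panel = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                name, fam, pheno, vids = line.rstrip("\n").split("\t")
                ids = [int(x) for x in vids.split(",")] if vids else []
                arch = RepeatArchitecture(
                    gene_id=name,
                    family_id=fam,
                    repeats=[(v, frozenset()) for v in ids],
                )
                panel.add(name, arch, pheno)
        return panel


@dataclass
class AlleleCall:
    query: str
    exact_match: str | None
    phenotype: str  # panel phenotype for exact matches, else "unknown"
    nearest: list[tuple[str, int, list[EditOp]]]
    verdict: str  # disrupted | non-candidate | candidate


@dataclass(frozen=True)
class FamilyRule:
    """Necessary repeat-count condition for a reactive allele."""

    min_repeats: int
    max_repeats: int | None = None  # None = unbounded above


# het-e: reactive alleles need >= 10 HIC repeats (known reactive alleles
# span 10-12); het-d: all known reactive alleles have exactly 11.
DEFAULT_FAMILY_RULES: dict[str, FamilyRule] = {
    "het-e": FamilyRule(min_repeats=10),
    "het-d": FamilyRule(min_repeats=11, max_repeats=11),
}


def functionality_screen(
    arch: RepeatArchitecture,
    rules: dict[str, FamilyRule] | None = None,
) -> str:
    """disrupted / non-candidate / candidate.

    Disruption flags dominate; then the family repeat-count rule.
    "candidate" is a necessary-conditions verdict only, never a
    reactivity prediction.
    """
    if rules is None:
        rules = DEFAULT_FAMILY_RULES
    rule = rules.get(arch.family_id)
    if rule is None:
        raise ValueError(f"no repeat-count rule configured for {arch.family_id!r}")
    if arch.is_disrupted():
        return "disrupted"
    n = arch.n_repeats
    if n < rule.min_repeats:
        return "non-candidate"
    if rule.max_repeats is not None and n > rule.max_repeats:
        return "non-candidate"
    return "candidate"


def assign_allele(
    query: RepeatArchitecture,
    panel: AllelePanel,
    k: int = 3,
    rules: dict[str, FamilyRule] | None = None,
    force: bool = False,
) -> AlleleCall:
    """Match a query barcode against the reference panel.

    A distance-0 entry is an exact match and inherits its phenotype;
    otherwise the k nearest entries are reported with their edit
    scripts and the phenotype stays "unknown" ("similar to" is as far
    as sequence alone can go).  Ties are ordered name-lexicographically.
    """
    candidates = panel.for_family(query.family_id)
    if not candidates:
        raise ValueError(f"panel has no entries for family {query.family_id!r}")
    scored = []
    for name, arch, pheno in candidates:
        dist, script = compare_architectures(query, arch, force=force)
        scored.append((dist, name, script, pheno))
    scored.sort(key=lambda x: (x[0], x[1]))
    exact = [x for x in scored if x[0] == 0]
    verdict = functionality_screen(query, rules=rules)
    if exact:
        dist, name, script, pheno = exact[0]
        return AlleleCall(
            query=query.gene_id,
            exact_match=name,
            phenotype=pheno,
            nearest=[(name, 0, script)],
            verdict=verdict,
        )
    return AlleleCall(
        query=query.gene_id,
        exact_match=None,
        phenotype="unknown",
        nearest=[(name, dist, script) for dist, name, script, _ in scored[:k]],
        verdict=verdict,
    )
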
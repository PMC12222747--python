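"""Generate a small cohort of synthetic HNWD-like alleles.

Each allele is flank + tandem 126-bp WD40 repeats + flank, with a known
planted barcode of repeat variants; one allele also receives an unequal
crossover duplication and a stop-codon disruption.
"""

from hicrepeats.simulate import (
    SimulationConfig,
    apply_unequal_crossover,
    build_variant_library,
    generate_allele,
    inject_disruption,
)

cfg = SimulationConfig(seed=42, variant_library_size=10)
library = build_variant_library(cfg)
print(f"variant library: {len(library)} distinct 7-aa signatures")
print("  first three:", ", ".join(sig for sig, _ in library[:3]))

allele = generate_allele(cfg, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 1], "demo", library)
print(f"\nallele {allele.allele_id}: {allele.n_repeats} repeats, "
      f"{len(allele.full_sequence)} nt total")

dup = apply_unequal_crossover(allele, 4, 1, "duplication")
print(f"after duplicating repeat 4: {dup.n_repeats} repeats, "
      f"barcode {dup.variant_ids}")

broken = inject_disruption(dup, 6, "stop", cfg)
print(f"after planting a stop in repeat 6: events = "
      f"{[e.kind for e in broken.events]}")

# The barcode is the ground truth that detection and classification
# must recover; the events list is what the disruption flags must find.
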
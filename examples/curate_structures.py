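"""Dataset curation: resolution/length filters and redundancy removal.

Parses a mixture of toy complexes, drops chains with resolution worse
than 2.5 Å or fewer than 30 residues, and greedily removes chains more
than 30% identical to an already-kept chain.
"""

from nucsite import (
    FixtureSpec,
    apply_structure_filters,
    parse_complex,
    remove_redundancy,
)
from nucsite.structure_io import write_manifest
from nucsite.synthetic import make_toy_complex

chains = []
# three good chains, one low-resolution copy, one short chain
for i, (length, resolution, seed) in enumerate(
    [(40, 1.8, 1), (40, 1.8, 2), (36, 2.5, 3), (40, 3.2, 4), (20, 1.5, 5)]
):
    spec = FixtureSpec(n_proteins=1, chain_length=length, n_binding=3,
                       seed=seed, resolution=resolution)
    parsed, _ = parse_complex(make_toy_complex(spec, 0))
    parsed[0].structure_id = f"S{i:03d}"
    chains.append(parsed[0])

print(f"parsed {len(chains)} chains")
kept = apply_structure_filters(chains, max_resolution=2.5, min_length=30)
print(f"after resolution <= 2.5 A and length >= 30 filters: {len(kept)} chains")
unique = remove_redundancy(kept, identity_cutoff=0.30)
print(f"after 30% identity redundancy removal: {len(unique)} chains\n")
print(write_manifest(unique))
print("random toy sequences rarely exceed 30% identity, so the filter "
      "mainly removes the low-resolution and short chains here")
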
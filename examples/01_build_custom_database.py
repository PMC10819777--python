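"""Build a project-specific classification library from a profile.

A synthetic community stands in for a real project: a taxonomy of three
genera, a merged taxonomic profile in which only some species were
detected, and a reference catalog holding one genome sequence per
species. The keep-list derived from the profile — at species or genus
granularity — selects which catalog sequences enter the library.
"""

import taxdiv as td
from taxdiv.synth import CommunityDesign

# a taxonomy of 3 genera with 4 + 3 + 2 species
tax, by_genus = td.random_taxonomy([4, 3, 2], seed=1)
species = [s for genus in by_genus for s in genus]

# simulate relative abundances, then silence all but three species so the
# profile "detects" one species from each of the first two genera only
rel = td.simulate_abundances(
    CommunityDesign(9, (9,), n_samples=4, seed=1), species_ids=species
)
detected = {by_genus[0][0], by_genus[0][1], by_genus[1][0]}
rel.loc[[s for s in species if s not in detected]] = 0.0

profile = td.read_merged_profile(td.write_fixture_profile(rel, tax))
names = td.species_name_map(tax)
fasta, correspondence = td.random_catalog_text(species, seed=1)
catalog = td.read_catalog(fasta, correspondence)

for level in ("species", "genus"):
    keep = td.build_keep_list(profile, names, tax, set(species), level=level)
    library = td.filter_catalog(catalog, keep)
    lib_fasta, lib_map = td.write_library(library, style="map-file")
    print(f"{level:>7}-level keep-list: {sorted(keep.tax_ids)}")
    print(f"        library: {len(library)} of {len(catalog)} sequences, "
          f"map consistent: {td.audit_library(catalog, lib_map) == []}")

# The species-level list holds exactly the 3 detected species; the
# genus-level list additionally pulls in their undetected congeners
# (7 species across the two detected genera), leaving the third genus out.
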
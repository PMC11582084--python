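"""Parse karyotype formulae and derive the six karyotype traits.

Loads the packaged leafcutting-ant cytogenetic table, shows how a
diploid formula string maps to the haploid trait vector (chromosome
number n, per-morphology counts nm/nsm/nst/nt, fundamental number fn),
and flags published rows whose printed fn disagrees with the
two-armed-m/sm/st convention.
"""

from karyoevol.karyotypes import (fundamental_number, load_fixture,
                                  parse_formula, trait_table,
                                  traits_from_counts)

counts = parse_formula("12 m + 10sm + 14st + 2 t")  # Acromyrmex balzani
traits = traits_from_counts(counts)
print(f"formula counts: {counts}")
print(f"traits: n={traits.n} nm={traits.nm} nsm={traits.nsm} "
      f"nst={traits.nst} nt={traits.nt} fn={traits.fn} (diploid arms)")

records = load_fixture()
print(f"\npackaged table: {len(records)} records, "
      f"{sum(r.group == 'leafcutting' for r in records)} leafcutting")
for rec in records:
    if not rec.fn_consistent:
        print(f"  flagged: {rec.taxon} ({rec.locality}) prints fn="
              f"{rec.fn_printed}, convention gives "
              f"{fundamental_number(rec.formula)}")

table = trait_table()  # one preferred record per species
print(f"\nanalysis table: {len(table)} species x {table.shape[1] - 1} traits")
print(table.head(4).to_string(index=False))
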
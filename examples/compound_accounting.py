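"""Detection-flag accounting: where do the formula's compounds end up?

Loads the packaged 97-compound worked-example table and partitions it by
detection pattern over {extract, plasma, feces}.
"""

from focuspharm import load_mzrw_fixtures, venn_partition

fx = load_mzrw_fixtures()
vp = venn_partition(fx.compounds)

herb_counts: dict[str, int] = {}
for r in fx.compounds:
    herb_counts[r.herb] = herb_counts.get(r.herb, 0) + 1

print(f"compounds identified: {len(fx.compounds)}")
print(f"per herb: {herb_counts}")
print(f"in rat plasma: {vp.set_sizes['plasma']}")
print(f"in rat feces:  {vp.set_sizes['feces']}")
print(f"in both:       {vp.in_sets('plasma', 'feces')}")
print(f"feces only:    {vp.region('feces')} (a metabolite absent from the extract)")

# The numbers describe oral bioavailability at a glance: roughly a third of
# the extract compounds are absorbed (plasma), a handful transit to feces,
# and one compound appears only as a gut metabolite.
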
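"""Free-energy and mutagenic-potential profile across a helical turn.

Uses the packaged dyad-site table: converts each position's half-life
to a rate constant, expresses it as a transition-state free-energy
difference from free DNA (37 degC), and scores mutagenic potential as
relative photoproduct yield x relative deamination rate.  Positive ddG
means faster deamination than free DNA; potential > 1 means the
position is a worse mutation hotspot than free DNA.
"""

from nucleocpd import (
    DEAMINATION_T_K,
    average_potential,
    ddg_from_rates,
    half_life_to_rate,
    relative_potential,
    site_table,
)

table = site_table()
free = table["Free ds1-10"]
k_free = half_life_to_rate(free.half_life_h)

print("pos  k(/h)   ddG(kcal/mol)  yield_fold  rate_fold  potential")
comparisons = []
for rec in sorted(
    (r for r in table.values() if r.context == "TmCG" and r.in_nucleosome),
    key=lambda r: r.position,
):
    k = half_life_to_rate(rec.half_life_h)
    ddg = ddg_from_rates(k, k_free, DEAMINATION_T_K).ddg_kcal_mol
    comp = relative_potential(
        rec.yield_percent, free.yield_percent, k, k_free, position=rec.position
    )
    comparisons.append(comp)
    print(
        f"{rec.position:3d}  {k:.4f}  {ddg:+12.2f}  {comp.yield_fold:10.2f}"
        f"  {comp.rate_fold:9.2f}  {comp.potential:9.2f}"
    )

print(
    f"\naverage potential over the ten positions: "
    f"{average_potential(comparisons):.2f}x free DNA"
)
print(
    "(an unphased nucleosome is that much more mutagenic at this site "
    "than naked DNA, repair and replication aside)"
)
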
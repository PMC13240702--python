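"""Chronic and acute dietary risk quotients for wheat consumers.

Evaluates flufenacet (ADI 0.005, ARfD 0.017 mg/kg bw) and diflufenican
(ADI 0.2, no ARfD set) for the general adult consumer and for children
under six, using field residue statistics censored at the 0.01 mg/kg
LOQ — terminal grain residues were all below the LOQ, so STMR and HR
are conservatively maximized to it.
"""

from residuecrop import PesticideToxProfile, PopulationGroup, ResidueSummary, assess

adult = PopulationGroup("adult_general", body_weight_kg=63.0,
                        daily_intake_kg=0.1385, large_portion_kg=0.73296)
child = PopulationGroup("child_under_6", body_weight_kg=16.1,
                        large_portion_kg=0.0258)
summary = ResidueSummary(stmr=0.01, hr=0.01, censored_at_loq=True)

for profile in (
    PesticideToxProfile("diflufenican", adi=0.2, arfd=None, loq=0.01),
    PesticideToxProfile("flufenacet", adi=0.005, arfd=0.017, loq=0.01),
):
    print(profile.name)
    for result in assess(profile, summary, [adult, child]):
        row = result.rounded()

        def pct(x):
            return f"{x}%" if isinstance(x, float) else str(x)

        print(f"  {row['group']:14s} RQc = {pct(row['rqc_percent'])}  "
              f"RQa = {pct(row['rqa_percent'])}  acceptable = {row['acceptable']}")

print("\nQuotients are intake relative to the toxicological reference value")
print("(x100%); below 100% is acceptable risk. 'None' marks quotients that")
print("cannot be computed (no tabulated mean intake for children); 'not")
print("applicable' marks acute assessment without an established ARfD.")
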
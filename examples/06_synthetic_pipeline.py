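"""Run the full pipeline on a small synthetic multi-species bundle.

Plants five ORFs in a five-species locus — two pass-everything plants
(one reference-flagged) and three single-fault decoys — then scans,
annotates, calibrates and runs the 9-step cascade, printing the funnel.
"""

from altorf import PlantSpec, SimulationConfig, make_bundle, run_pipeline

plants = [
    PlantSpec(plant_id="good0", aa_length=34, ref_flagged=True),
    PlantSpec(plant_id="good1", aa_length=42, strand="-", ref_flagged=True),
    PlantSpec(plant_id="lonely", aa_length=36, target_species=("simA",),
              intended_fate="min_species"),
    PlantSpec(plant_id="dark", aa_length=33, conservation_level=0.12,
              intended_fate="conservation"),
    PlantSpec(plant_id="silent", aa_length=35, expressed=False,
              intended_fate="read_support"),
]
bundle = make_bundle(SimulationConfig(seed=11, plants=plants))
res = run_pipeline(bundle)

print(res.funnel.to_frame().to_string(index=False))
print(f"\nfinal candidates: {sorted(res.final['orf_id'])}")
print(
    "\nThe funnel shrinks at the steps targeted by the decoys (the "
    "single-species plant at min_species, the unconserved one at "
    "conservation, the unexpressed one at read_support); background ORFs "
    "from the random filler drop at the conservation step. Exactly the "
    "two pass-everything plants survive, annotated with dN/dS in step 9."
)
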
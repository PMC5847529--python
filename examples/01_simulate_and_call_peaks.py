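"""Simulate a capture design with planted interaction peaks and call them.

Builds a 10-chromosome synthetic genome (HindIII-like 4 kb fragments,
20 capture regions, two replicates), plants fifty 8-fold-enriched fragment
pairs, runs the interactability filter and the NB-background peak caller,
and scores the calls against the known truth.
"""

from chicpeaks import (
    call_cell_line,
    preset_config,
    simulate_cell_line,
    simulate_fragment_map,
    truth_evaluation,
)

cfg = preset_config("power")
fm, regions, snps, loci = simulate_fragment_map(cfg, seed=1)
sim = simulate_cell_line(cfg, fm, seed=42)

res = call_cell_line(fm, loci, sim["pair_counts"], sim["trans_counts"], cell_line="example")
calls = res["calls"]
ev = truth_evaluation(calls, sim["truth"])

print(f"fragments: {len(fm)}  captured: {len(fm.captured_frag_ids())}  risk loci: {len(loci)}")
print(f"captured fragments excluded by interactability filter: {res['pct_excluded']:.1f}%")
print(f"candidate pairs tested: {len(calls)}")
print(f"significant peaks (FDR-adjusted p < 0.01): {int(calls['significant'].sum())}")
print(f"planted peaks recovered: {ev['true_positives']}/{ev['n_planted_detectable']}"
      f"  (sensitivity {ev['sensitivity']:.2f}, FDP {ev['fdp']:.3f})")
# sensitivity close to 1 and FDP well under 0.05 mean the background model
# separates genuine 8-fold enrichments from distance-decay noise
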
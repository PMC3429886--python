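"""How much sequence does a reliable FCGR tree need?

Records are shuffled, concatenated and cut to fixed lengths; topology
recovery is scored against the known generating tree at each length.  At
low divergence, short subsamples no longer resolve the topology while the
long ones do — the resolution/length trade-off of k-mer signatures.
"""

from cgrphylo import (
    SequenceRecord,
    compute_fcgr,
    evolve_sequences,
    neighbor_joining,
    robinson_foulds,
    shred_subsample,
    two_clade_scenario,
)
from cgrphylo.pipeline import point_distance_matrix

for target in (1_000, 10_000, 50_000):
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        scn = two_clade_scenario(seed=seed, root_length=50_000, rate=0.001)
        profiles = []
        for label, seq in evolve_sequences(scn):
            records = [SequenceRecord(f"c{i}", seq[i : i + 5000])
                       for i in range(0, len(seq), 5000)]
            ss = shred_subsample(records, target, seed=seed, label=label)
            profiles.append((label, compute_fcgr(ss, k=8)))
        dm = point_distance_matrix(profiles, "euclidean")
        hits += robinson_foulds(neighbor_joining(dm), scn.tree) == 0
    print(f"subsample {target:>6} nt: generating topology recovered in "
          f"{hits}/{n_seeds} runs (k=8, very low divergence)")
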
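"""A three-round active-learning campaign on a synthetic landscape.

Round 1 trains on a screening-style table; each subsequent round scores the
whole design space, selects a diverse candidate batch (top predictions +
cluster representatives + random draws), "measures" it on the hidden
landscape and retrains.  The pooled cross-validation correlation is tracked
per round.
"""

from teploop import DesignContext, ModelConfig, SelectionPolicy, run_campaign
from teploop.analysis import position_frequency_matrix
from teploop.synthetic import LandscapeSpec, initial_screening_table, make_landscape

context = DesignContext.build(alphabet="ADIKNS")  # small space for speed
oracle = make_landscape(LandscapeSpec(seed=555), scales=context.scales)
initial = initial_screening_table(
    oracle, seed=5, n_total=60, n_screen=400, n_top=40, alphabet="ADIKNS"
)

policy = SelectionPolicy(pool_size=200, batch_size=20, n_top=10,
                         n_cluster_reps=6, n_random=4, k_clusters=6)
history = run_campaign(
    initial, oracle, n_rounds=3, policy=policy,
    config=ModelConfig(n_trees=200), context=context,
    batch_sizes=[20, 10, 0], seed=9,
)

print(history.summary().to_string(index=False))
# n_training grows by each measured batch; pooled_r typically rises as the
# model sees more of the landscape.

pfm = position_frequency_matrix(history.rounds[-1].top100)
print(f"\nfreq(D, position 4) among top-100 predictions: {pfm.freqs.loc['D', 4]:.2f}")
# The landscape plants an aspartate bonus at position 4; a well-trained
# model concentrates D there, far above the uniform background.
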
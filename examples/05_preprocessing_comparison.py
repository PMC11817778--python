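"""Compare preprocessing methods (raw / SNV / MSC / SG) under PLSR.

For each target and method the pipeline fits a PLSR whose latent-variable
count is chosen by 5-fold cross-validation, then scores it on the held-out
Kennard-Stone prediction set.  Lower RMSEP / higher RP2 is better.
"""

from nirquant import PipelineConfig, run_preprocessing_comparison

config = PipelineConfig(seed=1, n_points=600, replicates_per_level=8)
table = run_preprocessing_comparison(config)
print(table.round(4).to_string(index=False))

best = table.loc[table.groupby("target")["RMSEP"].idxmin(), ["target", "model", "RMSEP"]]
print("\nbest method per target (lowest RMSEP):")
print(best.to_string(index=False))
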
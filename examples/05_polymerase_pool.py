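"""Limited-RNAPII-pool simulation of genome-wide premature termination.

Calibrates the initiation constant so baseline initiations occur every
2.5 s per gene, then introduces a premature termination site 10 kb into
every gene: long-gene bodies empty within one transit time and the
enlarged free pool speeds up re-initiation on all genes.
"""

import numpy as np

from ttquant.polsim import (
    SimConfig,
    calibrate_initiation_constant,
    mean_interinitiation,
    run_simulation,
)

cfg = SimConfig(seed=0)
c = calibrate_initiation_constant(cfg)
print(f"calibrated initiation constant: {c:.3e} /s per free polymerase per gene")

burn = max(cfg.gene_lengths) / cfg.speed_bp_s * 1.2
run_cfg = SimConfig(**{**cfg.__dict__, "initiation_constant": c,
                       "t_switch": burn + 500, "horizon": burn + 4000})
res = run_simulation(run_cfg, np.random.default_rng(0))

pre = mean_interinitiation(res, burn, run_cfg.t_switch)
post = mean_interinitiation(res, run_cfg.horizon - 800, run_cfg.horizon)
print(f"inter-initiation interval: {pre:.2f} s before the switch, {post:.2f} s after")

t_check = run_cfg.t_switch + (100_000 - cfg.premature_tts) / cfg.speed_bp_s + 30
gidx, pos = res.positions_at(t_check)
n_beyond = sum(1 for g, p in zip(gidx, pos)
               if res.gene_lengths[g] > cfg.premature_tts and p > cfg.premature_tts)
print(f"polymerases beyond the 10 kb site on long genes after one transit: {n_beyond}")
print(f"free pool: {res.free_pool_at(run_cfg.t_switch - 10)} before vs "
      f"{res.free_pool_at(run_cfg.horizon - 10)} after the switch")
print("Early termination recycles polymerases sooner, so the free pool grows "
      "and unaffected (short) genes can initiate faster — without any change "
      "to their own regulation.")
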
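"""The interpatient prior: pretrain on a cohort, reconstruct a held-out patient.

Shared network weights are pretrained jointly with one 16-dimensional latent
per patient (generative latent optimization) on sparse 10-view sinograms of a
cohort.  A held-out patient is then reconstructed twice from its 10-view
sinogram: finetuning from the shared checkpoint (with prior) and from a fresh
initialization (without).  The prior start is both faster (lower image MSE at
iteration 100) and better at the end of the budget.
"""

import neurec as nr
from neurec.model import ModelConfig

res = nr.ablation_experiment(
    n_train_patients=10, n_views=10, seed=5, size=48,
    pretrain_steps=800, recon_steps=200,
    model_config=ModelConfig(hidden_width=64, n_blocks=4, sine_omega=8.0),
)
trace_prior = res["with_prior"][1]
trace_no = res["without_prior"][1]
for t in (0, 50, 100, 200):
    print(f"iter {t:3d}: image MSE with prior {trace_prior.image_mse[t]:.4f}   "
          f"without {trace_no.image_mse[t]:.4f}")
truth = res["truth"]
print(f"final PSNR: with prior {nr.evaluate(res['with_prior'][0], truth).psnr_db:.2f} dB, "
      f"without {nr.evaluate(res['without_prior'][0], truth).psnr_db:.2f} dB")
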
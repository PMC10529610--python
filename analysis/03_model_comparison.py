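"""SWI model comparison: which learning model explains lifting agents?

Simulates 20 subjects from the 4-level HGF on the 32-trial SWI designs,
fits all four candidate models (HGF3, HGF4, Rescorla-Wagner, Sutton K1)
per subject by MAP, computes Laplace log-model evidences, and compares
them with random-effects Bayesian model selection at the model and
family level.  Writes the LME matrix and BMS summaries.
"""

from pathlib import Path

from sensolearn.study import swi_model_comparison

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

result = swi_model_comparison(n_subjects=20, seed=20230911, n_restarts=4)

result.lme.to_csv(OUT / "swi_lme_matrix.csv")
result.model_bms.to_frame().to_csv(OUT / "swi_bms_models.csv", index=False)
result.family_bms.to_frame().to_csv(OUT / "swi_bms_families.csv",
                                    index=False)

mean_lme = result.lme.mean()
print("mean LME per model:")
for m, v in mean_lme.items():
    print(f"  {m:>8}: {v:7.2f}")
print("model-level PXP:",
      {m: round(p, 3) for m, p in zip(result.model_bms.models,
                                      result.model_bms.pxp)})
print(f"hierarchical-family PXP: {result.family_pxp:.4f} "
      f"(BOR {result.family_bms.bor:.4f})")
print("=> the hierarchical (HGF) family is selected essentially with "
      "certainty; the two HGF depths are not separable from 32-trial "
      "series, which is why protection is reported at the family level")
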
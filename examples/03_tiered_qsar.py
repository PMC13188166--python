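"""Fit the two-tier PLS QSAR with its PCA domain of applicability and
predict a query compound in tandem."""

import io

from ttraop.curation import curate, parse_binding_table
from ttraop.descriptors import descriptor_table
from ttraop.qsar import fit_tiered, predict_tiered, stratified_split, evaluate
from ttraop.synth import GeneratorSpec, gen_binding_dataset

df, _ = gen_binding_dataset(GeneratorSpec(seed=1))
buf = io.StringIO(); df.to_csv(buf, index=False); buf.seek(0)
actives = [r for r in curate(parse_binding_table(buf))
           if r.binder_class != "inactive"]
desc = descriptor_table([(r.compound_id, r.smiles) for r in actives])

train, test = stratified_split(actives, test_size=10, seed=1,
                               keep_extremes_in_train=True)
model = fit_tiered(desc.loc[[r.compound_id for r in train]],
                   [r.pec50 for r in train], [r.binder_class for r in train])

t1 = model.tier1.training_metrics
print(f"Tier 1 (all actives):    R2={t1['r2']:.2f} RMSE={t1['rmse']:.2f} "
      f"Q2(LOO)={t1['q2_loo']:.2f}")
t2 = model.tier2.training_metrics
print(f"Tier 2 (medium+strong):  R2={t2['r2']:.2f} RMSE={t2['rmse']:.2f}")
ev = evaluate(model.tier1, desc.loc[[r.compound_id for r in test]],
              [r.pec50 for r in test])
print(f"Tier 1 test set:         R2={ev['r2']:.2f} RMSE={ev['rmse']:.2f}")

query = desc.loc[test[0].compound_id].to_dict()
pred = predict_tiered(model, query)
print(f"query {test[0].compound_id}: tier1 pEC50={pred['pec50_tier1']:.2f} "
      f"({pred['binder_class']}), in DoA1={pred['in_doa1']}, "
      f"tier2 pEC50={pred['pec50_tier2']:.2f}")
# Tier 1 places any PFAS in a binding-strength band; Tier 2 refines the
# estimate for medium/strong binders inside its narrower domain.
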
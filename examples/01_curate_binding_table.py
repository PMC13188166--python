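"""Curate a PFAS-hTTR binding table: salts out, duplicates collapsed,
EC50 converted to pEC50 with binder classes attached."""

from ttraop.synth import GeneratorSpec, gen_binding_dataset
from ttraop.curation import curate
import io
from ttraop.curation import parse_binding_table

df, _ = gen_binding_dataset(GeneratorSpec(seed=1, exact_duplicate_ec50=1.71))
buf = io.StringIO()
df.to_csv(buf, index=False)
buf.seek(0)

records = parse_binding_table(buf)
curated = curate(records)

print(f"{len(records)} rows in -> {len(curated)} curated compounds")
survivor = next(r for r in curated if r.name == "1,6-Diiodoperfluorohexane")
print(f"duplicate survivor: {survivor.name}, EC50 {survivor.ec50:.2f} uM "
      f"(pEC50 {survivor.pec50:.3f}, {survivor.binder_class})")
classes = {}
for r in curated:
    classes[r.binder_class] = classes.get(r.binder_class, 0) + 1
print("binder classes:", classes)
# The 80-row table loses 7 salt forms and 1 duplicate; the duplicate keeps
# the more potent (lower-EC50) measurement.
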
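"""Compute the named QSAR descriptors for a perfluorooctanoate anion."""

from ttraop.descriptors import compute_descriptors, standardize_structure

pfoa = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
mol = standardize_structure(pfoa, pH=7.0)   # carboxylate anion at pH 7
vec = compute_descriptors(mol, conformer_seed=7)

for name, value in vec.as_dict().items():
    print(f"{name:>14}: {value:.4f}" if isinstance(value, float)
          else f"{name:>14}: {value}")
# n_C / a_count / b_single grow with chain length; TPSA reflects the anionic
# head group; KierA1 is the alpha-corrected chain-shape index; E_vdw is the
# van der Waals energy (kcal/mol) of the minimized 3D conformer.
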
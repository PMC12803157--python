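"""Detect a planted catalytic arginine in a toy predicted complex.

Generates a toy GTP-bound reference GTPase and a predicted complex in
which residue 116 of the candidate-GAP chain is an arginine whose NH1
sits 3.0 Å from where the γ-phosphate lands after superposition — the
geometry that flags an "arginine finger", the hallmark of many GAPs.
"""

from denngap import (
    ToyComplexSpec,
    detect_arginine_finger,
    make_toy_complex,
    read_structure,
    superpose,
    transplant_ligand,
)

ref_text, model_text = make_toy_complex(ToyComplexSpec())
ref = read_structure(ref_text)
model = read_structure(model_text)

sup = superpose(ref, model, None, "G", "G")
print(f"superposed {sup.n_pairs} Cα pairs, rmsd {sup.rmsd:.4f} Å")

ligand = transplant_ligand(ref, sup)
calls = detect_arginine_finger(model, ligand, "A", cutoff=4.5)
for c in calls:
    print(
        f"ARG {c.res_number}: min guanidinium→γ-phosphate distance "
        f"{c.min_distance:.2f} Å, passes={c.passes}"
    )

print(
    "\nA passing call means an arginine guanidinium atom lies within 4.5 Å"
    "\nof the transplanted γ-phosphate — candidate catalytic arginine."
)
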
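"""Mesh convergence of the cut-plane bending moment.

Solves the same flexion step on three successively refined meshes and
reports the relative change of Mz between levels; the construct is
considered converged when the finest step changes the moment by < 5%.
"""

from osteoload import MeshParams, check_convergence, default_construct
from osteoload.pipeline import bending_moment_pipeline

levels = [MeshParams(scale_factor=s) for s in (16.0, 8.0, 4.0)]
res = check_convergence(default_construct(), levels, bending_moment_pipeline)

print("scale   edge target (plate)   Mz [N*mm]")
for p, m in zip(levels, res["moments"]):
    print(f"{p.scale_factor:5.1f}   {0.25 * p.scale_factor:8.2f} mm        {m:8.4f}")
print("\nrelative changes between levels:",
      [f"{100 * r:.2f}%" for r in res["relative_changes"]])
print("converged (<5% at the finest step):", res["converged"])
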
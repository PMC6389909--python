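"""File-based workflow: plate export + ligand map in, report out.

Writes a simulated plate to the wide CSV format RT-PCR instruments
export (temperature column plus one column per well) with its ligand
map, reads both back, runs the pipeline at two slice temperatures, and
writes the JSON/CSV report.  Demonstrates that K_d estimated at
different slice temperatures tracks the simulator's own K_d(T).
"""

import json
import tempfile
from pathlib import Path

from dsf_isofit import (
    AssayConfig,
    c_to_k,
    generate_dataset,
    kd_at_temperature,
    mbp_like_spec,
    read_melt_table,
    run_pipeline,
    write_ligand_map,
    write_melt_table,
    write_report,
)

spec = mbp_like_spec(noise_sigma=0.01, seed=7)
workdir = Path(tempfile.mkdtemp())
write_melt_table(workdir / "melt_curves.csv", generate_dataset(spec))
write_ligand_map(workdir / "ligand_map.csv", generate_dataset(spec))
print(f"wrote plate files under {workdir}")

curves = read_melt_table(workdir / "melt_curves.csv",
                         workdir / "ligand_map.csv", normalized=True)
config = AssayConfig(protein_conc_total=spec.p_total,
                     slice_temperatures=[50.0, 53.0], dcp_u=spec.dcp_u)
report = run_pipeline(config, curves)
write_report(report, workdir / "out")

payload = json.loads((workdir / "out" / "report.json").read_text())
for t_label, entry in payload["isothermal"].items():
    truth = float(kd_at_temperature(spec, c_to_k(float(t_label)))) * 1e6
    print(f"{t_label} C: K_d = {entry['K_d_M'] * 1e6:.2f} uM "
          f"(simulator truth {truth:.2f} uM), K_U = {entry['K_U']:.2f}")
print(f"report files: {sorted(p.name for p in (workdir / 'out').iterdir())}")
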
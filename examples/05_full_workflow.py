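"""Run the whole planning workflow for one synthetic subject.

Hip/knee/ankle pseudo-CT volumes in, implant designs out: segmentation,
partial-data reconstruction of both bones, landmark extraction, resection
planning and component design, with a machine-readable report.  Takes a
few minutes on one CPU.
"""

import json

import numpy as np

from kneeforge import pipeline, ssm, synthbone

femur_t = synthbone.make_template("femur")
tibia_t = synthbone.make_template("tibia")
femur_model = ssm.truncate(
    ssm.build_model(ssm.CorrespondedSet.from_population(
        synthbone.sample_population(femur_t, 20, 6, 2.0, seed=7))), 0.99
)
tibia_model = ssm.truncate(
    ssm.build_model(ssm.CorrespondedSet.from_population(
        synthbone.sample_population(tibia_t, 20, 6, 2.0, seed=8))), 0.99
)

fb = synthbone.sample_population(femur_t, 2, 6, 2.0, seed=21)[0]
tb = synthbone.sample_population(tibia_t, 2, 6, 2.0, seed=22)[0]
fb = synthbone.position_joint(fb, tb)
volumes = {
    acq: vol
    for acq, (vol, _) in synthbone.subject_volumes(
        fb, tb, spacing=1.5, noise_sd=30.0, seed=5
    ).items()
}
print("acquisitions:", {k: v.shape for k, v in volumes.items()})

outputs = pipeline.run_workflow(
    volumes, {"femur": femur_model, "tibia": tibia_model}
)
print(json.dumps(
    {k: v["status"] for k, v in outputs.report.stages.items()}, indent=1
))
print("metrics:", json.dumps(outputs.report.metrics, indent=1))

# score against the generator's ground truth
from kneeforge.metrics import surface_distance

for kind, truth in (("femur", fb), ("tibia", tb)):
    rep = surface_distance(outputs.fits[kind].reconstructed, truth.mesh)
    lme = np.mean([
        np.linalg.norm(outputs.landmarks[kind][n].point
                       - truth.landmarks[n].point)
        for n in truth.landmarks.names
    ])
    print(f"{kind}: reconstruction RMSE {rep.rmse:.2f} mm, "
          f"landmark mean error {lme:.2f} mm")
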
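"""Population trajectories in the task-variable subspace.

Defines direction and value axes by per-unit regression, orthogonalizes
them, and shows that trajectory endpoints at saccade onset separate with
the difference in chosen subjective value.
"""

import numpy as np

import seqsel
from seqsel.state_space import (
    build_design,
    condition_average,
    endpoint_distance_regression,
    fit_task_axes,
    project_trajectories,
    response_tensor,
    zscore_unit_responses,
)

session = seqsel.make_session(n_blocks=30, n_units=60, seed=3)
choice = [t for t in session["trials"] if t.trial_type == "choice"]
psi = session["bp"].psi

tensor, times = response_tensor(session["neurons"], choice)
z, keep = zscore_unit_responses(tensor)
axes = fit_task_axes(z[keep], build_design(choice, psi), times)
print("axis selection times (max coefficient norm):", axes.t_var_max)

Xc, info = condition_average(z[keep], choice, psi, by="direction_x_value_level")
traj = project_trajectories(Xc, axes)
t0 = int(np.argmin(np.abs(times)))
res = endpoint_distance_regression(
    traj[:, :, t0],
    np.array([c["chosen_value"] for c in info]),
    [c["direction"] for c in info],
)
print(f"endpoint distance vs chosen-value difference: slope {res.slope:.2f}, "
      f"t = {res.t_stat:.1f}, p = {res.p_value:.2g} ({res.n_pairs} pairs)")
print("A positive slope means states for differently valued chosen options "
      "stay separated in the task subspace at movement time.")
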
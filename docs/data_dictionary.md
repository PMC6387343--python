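# Data dictionary

Canonical feature columns of the per-subject feature table. The two
assessor-recorded standard clinical measures `cst30_repetitions_manual`
(count) and `tug_duration_manual` (s) complete the table.

## 30-s Chair Stand (21 features)

| column | subphase | sensor.axis | statistic | units |
|---|---|---|---|---|
| `cst_repetitions` | Total | - | repetitions | count |
| `cst_sts_duration_mean` | SitToStand | - | duration | s |
| `cst_sts_duration_sd` | SitToStand | - | sd_duration | s |
| `cst_sts_njs_acc_ap` | SitToStand | acc.AP | njs | m |
| `cst_sts_rms_acc_ap` | SitToStand | acc.AP | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_sts_njs_acc_ml` | SitToStand | acc.ML | njs | m |
| `cst_sts_rms_acc_ml` | SitToStand | acc.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_sts_njs_acc_v` | SitToStand | acc.V | njs | m |
| `cst_sts_rms_acc_v` | SitToStand | acc.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_sts_rms_gyr_ml` | SitToStand | gyr.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_sts_rms_gyr_v` | SitToStand | gyr.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_st2si_duration_mean` | StandToSit | - | duration | s |
| `cst_st2si_duration_sd` | StandToSit | - | sd_duration | s |
| `cst_st2si_njs_acc_ap` | StandToSit | acc.AP | njs | m |
| `cst_st2si_rms_acc_ap` | StandToSit | acc.AP | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_st2si_njs_acc_ml` | StandToSit | acc.ML | njs | m |
| `cst_st2si_rms_acc_ml` | StandToSit | acc.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_st2si_njs_acc_v` | StandToSit | acc.V | njs | m |
| `cst_st2si_rms_acc_v` | StandToSit | acc.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_st2si_rms_gyr_ml` | StandToSit | gyr.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `cst_st2si_rms_gyr_v` | StandToSit | gyr.V | rms | m/s^2 (acc) or deg/s (gyr) |

## Timed Up and Go (28 features)

| column | subphase | sensor.axis | statistic | units |
|---|---|---|---|---|
| `tug_total_duration` | Total | - | total_duration | s |
| `tug_sit_to_walk_duration` | SitToWalk | - | duration | s |
| `tug_walk_duration` | Walk | - | duration | s |
| `tug_turn180_duration` | Turn180 | - | duration | s |
| `tug_turn_to_sit_duration` | TurnToSit | - | duration | s |
| `tug_walk_steps` | Walk | acc.V | steps | count |
| `tug_turn180_steps` | Turn180 | acc.V | steps | count |
| `tug_sit_to_walk_rms_acc_ap` | SitToWalk | acc.AP | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_sit_to_walk_rms_acc_ml` | SitToWalk | acc.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_sit_to_walk_rms_acc_v` | SitToWalk | acc.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_walk_rms_acc_ap` | Walk | acc.AP | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_walk_rms_acc_ml` | Walk | acc.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_walk_rms_acc_v` | Walk | acc.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_turn_to_sit_rms_acc_ap` | TurnToSit | acc.AP | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_turn_to_sit_rms_acc_ml` | TurnToSit | acc.ML | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_turn_to_sit_rms_acc_v` | TurnToSit | acc.V | rms | m/s^2 (acc) or deg/s (gyr) |
| `tug_sit_to_walk_njs_acc_ap` | SitToWalk | acc.AP | njs | m |
| `tug_sit_to_walk_njs_acc_ml` | SitToWalk | acc.ML | njs | m |
| `tug_sit_to_walk_njs_acc_v` | SitToWalk | acc.V | njs | m |
| `tug_turn_to_sit_njs_acc_ap` | TurnToSit | acc.AP | njs | m |
| `tug_turn_to_sit_njs_acc_ml` | TurnToSit | acc.ML | njs | m |
| `tug_turn_to_sit_njs_acc_v` | TurnToSit | acc.V | njs | m |
| `tug_turn180_angular_njs` | Turn180 | gyr.V | angular_njs | - |
| `tug_turn180_mean_velocity` | Turn180 | gyr.V | mean_velocity | deg/s |
| `tug_turn180_max_velocity` | Turn180 | gyr.V | max_velocity | deg/s |
| `tug_tts_turning_angular_njs` | TurnToSitTurning | gyr.V | angular_njs | - |
| `tug_tts_turning_mean_velocity` | TurnToSitTurning | gyr.V | mean_velocity | deg/s |
| `tug_tts_turning_max_velocity` | TurnToSitTurning | gyr.V | max_velocity | deg/s |

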
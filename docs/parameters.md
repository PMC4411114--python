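# Parameter name mapping

Parameters are addressed by canonical snake_case keys; the spelled-out
names of the published default table (including their mixed
"Thx"/"THx" capitalization) are accepted everywhere and normalized via
`hlsim.normalize_key`. Pulse schedules expose three keys each
(`*_time`, `*_dur`, `*_intens`; the long forms `*_duration` and
`*_intensity` are also accepted).

| Published name | Canonical key | Default |
|---|---|---|
| CSC cap | `csc_cap` | 1e-09 |
| CSC death | `csc_death` | 0.01 |
| CSC diff | `csc_diff` | 0.002 |
| CSC growth | `csc_growth` | 0.01 |
| CSC Thx dur | `csc_thx_dur` | 100 |
| CSC THx intens | `csc_thx_intens` | 0 |
| CSC THx time | `csc_thx_time` | 400 |
| CTAC cap | `ctac_cap` | 1e-09 |
| CTAC death | `ctac_death` | 0.03 |
| CTAC diff | `ctac_diff` | 0.91 |
| CTAC growth | `ctac_growth` | 0.9 |
| CTAC Thx dur | `ctac_thx_dur` | 100 |
| CTAC THx intens | `ctac_thx_intens` | 0 |
| CTAC THx time | `ctac_thx_time` | 400 |
| Help for CSC | `help_for_csc` | 0.001 |
| Help for CTAC | `help_for_ctac` | 0.001 |
| Help for Killer Cells | `help_for_killer` | 1e-05 |
| Help for MTC | `help_for_mtc` | 0.001 |
| Helper cap | `helper_cap` | 1e-09 |
| Helper death | `helper_death` | 1e-05 |
| Helper stim by CSC | `helper_stim_by_csc` | 0.001 |
| Helper stim by CTAC | `helper_stim_by_ctac` | 0.001 |
| Helper stim by MTC | `helper_stim_by_mtc` | 0.001 |
| Helper Thx dur | `helper_thx_dur` | 100 |
| Helper THx intens | `helper_thx_intens` | 0 |
| Helper THx time | `helper_thx_time` | 400 |
| ImmunoTHx1 dur | `immuno1_dur` | 1 |
| ImmunoTHx1 intens | `immuno1_intens` | 0 |
| ImmunoTHx1 time | `immuno1_time` | 300 |
| ImmunoTHx2CSC dur | `immuno2_csc_dur` | 3000 |
| ImmunoTHx2CSC intens | `immuno2_csc_intens` | 0 |
| ImmunoTHx2CSC time | `immuno2_csc_time` | 1000 |
| ImmunoTHx2CTAC dur | `immuno2_ctac_dur` | 3000 |
| ImmunoTHx2CTAC intens | `immuno2_ctac_intens` | 0 |
| ImmunoTHx2CTAC time | `immuno2_ctac_time` | 1000 |
| ImmunoTHx2MTC dur | `immuno2_mtc_dur` | 3000 |
| ImmunoTHx2MTC intens | `immuno2_mtc_intens` | 0 |
| ImmunoTHx2MTC time | `immuno2_mtc_time` | 1000 |
| Initial CSC | `initial_csc` | 10 |
| Initial CTAC | `initial_ctac` | 10 |
| Initial Helper Cells | `initial_helper` | 10 |
| Initial Killer Cells | `initial_killer` | 10 |
| Initial MTC | `initial_mtc` | 10 |
| Initial Regulatory Cells | `initial_regulator` | 10 |
| Kill of CSC | `kill_of_csc` | 1e-06 |
| Kill of CTAC | `kill_of_ctac` | 1e-06 |
| Kill of MTC | `kill_of_mtc` | 1e-06 |
| Killer cap | `killer_cap` | 1e-09 |
| Killer death | `killer_death` | 1e-05 |
| Killer stim by CSC | `killer_stim_by_csc` | 0.0001 |
| Killer stim by CTAC | `killer_stim_by_ctac` | 0.0001 |
| Killer stim by MTC | `killer_stim_by_mtc` | 0.02 |
| Killer THx dur | `killer_thx_dur` | 100 |
| Killer THx intens | `killer_thx_intens` | 0 |
| Killer THx time | `killer_thx_time` | 400 |
| MTC cap | `mtc_cap` | 1e-09 |
| MTC death | `mtc_death` | 0.5 |
| MTC growth | `mtc_growth` | 0 |
| MTC Thx dur | `mtc_thx_dur` | 100 |
| MTC THx intens | `mtc_thx_intens` | 0 |
| MTC THx time | `mtc_thx_time` | 400 |
| Regulation of Helper Cells | `regulation_of_helper` | 0.0001 |
| Regulation of Killer Cells | `regulation_of_killer` | 0.5 |
| Regulator cap | `regulator_cap` | 0.0001 |
| Regulator death | `regulator_death` | 1e-05 |
| Regulator stim by CSC | `regulator_stim_by_csc` | 0.001 |
| Regulator stim by CTAC | `regulator_stim_by_ctac` | 0.001 |
| Regulator stim by MTC | `regulator_stim_by_mtc` | 0.0001 |
| Regulator Thx dur | `regulator_thx_dur` | 100 |
| Regulator THx intens | `regulator_thx_intens` | 0 |
| Regulator THx time | `regulator_thx_time` | 400 |
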
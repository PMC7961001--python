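sustaining_proliferative_signaling	synthetic illustrative set	G00001	G00002	G00003	G00004	G00005	G00006	G00007	G00008
resisting_cell_death	synthetic illustrative set	G00009	G00010	G00011	G00012	G00013	G00014	G00015	G00016
inducing_angiogenesis	synthetic illustrative set	G00017	G00018	G00019	G00020	G00021	G00022	G00023
genome_instability	synthetic illustrative set	G00024	G00025	G00026	G00027	G00028	G00029	G00030	G00031	G00032
evading_growth_suppressors	synthetic illustrative set	G00033	G00034	G00035	G00036	G00037	G00038
enabling_replicative_immortality	synthetic illustrative set	G00039	G00040	G00041	G00042	G00043	G00044	G00045
deregulation_cellular_energetics	synthetic illustrative set	G00046	G00047	G00048	G00049	G00050	G00051	G00052
activating_invasion_metastasis	synthetic illustrative set	G00053	G00054	G00055	G00056	G00057	G00058	G00059	G00060	G00001	G00024
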
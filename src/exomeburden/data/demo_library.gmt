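kidney_cancer_development	synthetic demo set	G0003	G0007	G0010	G0015	G0025	G0033	G0036	G0042	G0055	G0071
carcinoma_development	synthetic demo set	G0005	G0007	G0010	G0013	G0016	G0020	G0028	G0030	G0031	G0042	G0046	G0056	G0067	G0069	G0074
nephron_transport	synthetic demo set	G0002	G0004	G0006	G0008	G0012	G0027	G0035	G0038	G0048	G0049	G0065	G0079
cell_adhesion	synthetic demo set	G0018	G0021	G0022	G0026	G0032	G0043	G0045	G0050	G0051	G0053	G0057	G0058	G0061	G0062	G0068	G0073	G0077	G0078
ciliary_assembly	synthetic demo set	G0001	G0014	G0017	G0023	G0041	G0044	G0059	G0070	G0072	G0075	G0076	G0080
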
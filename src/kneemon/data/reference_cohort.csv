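subject_id,group_label,week_label,avg_rom_deg,mav_vl_v,mav_vm_v,rms_vl_v,rms_vm_v
H1,healthy,single,87.3,0.189,0.126,0.266,0.175
H2,healthy,single,87.5,0.173,0.106,0.248,0.15
H3,healthy,single,88.6,0.132,0.093,0.202,0.141
H4,healthy,single,88.5,0.08,0.048,0.118,0.068
H5,healthy,single,85.4,0.133,0.057,0.199,0.078
H6,healthy,single,89.1,0.11,0.11,0.155,0.152
P1,bone_joint,first,87.5,0.046,0.036,0.063,0.05
P2,bone_joint,first,80.1,0.083,0.068,0.12,0.094
P3,bone_joint,first,88.9,0.088,0.104,0.127,0.152
P4,neuro,first,74.2,0.025,0.022,0.044,0.04
P5,neuro,first,78.6,0.043,0.036,0.062,0.05
P6,neuro,first,83.3,0.043,0.027,0.063,0.037
P1,bone_joint,last,88.4,0.083,0.078,0.117,0.112
P2,bone_joint,last,85.1,0.091,0.067,0.134,0.096
P3,bone_joint,last,88,0.1,0.111,0.148,0.163
P4,neuro,last,77.6,0.04,0.033,0.063,0.049
P5,neuro,last,80.1,0.073,0.041,0.11,0.059
P6,neuro,last,86.7,0.082,0.039,0.119,0.052
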
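identifier	class
K00845	sugar
K00847	sugar
K00850	sugar
K01810	sugar
K00134	sugar
K02777	sugar
K02778	sugar
K02779	sugar
K02790	sugar
K02791	sugar
K01222	sugar
K01785	sugar
K00036	sugar
K01835	sugar
K15778	sugar
K11103	acid
K11688	acid
K11689	acid
K11690	acid
K00024	acid
K00025	acid
K00029	acid
K01676	acid
K01679	acid
K00239	acid
K00244	acid
K03303	acid
K14393	acid
K01647	acid
K09477	acid
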